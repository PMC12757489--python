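#!/usr/bin/env python
"""Correlation screens.

Correlates each common protein's EV levels against its paired tissue
levels (the compartment-exchange screen) and runs the peptidome-wide
correlation heatmap with sign-reversal detection between controls and
early disease. Writes results/cross_compartment.tsv, heatmap_table.tsv,
reversals.tsv.
"""

from pathlib import Path

import pandas as pd

from omdpipe.correlation import (
    cross_compartment_correlation,
    peptide_heatmap_table,
    results_to_frame,
)
from omdpipe.synthetic_data import SyntheticTruth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    design = pd.read_csv(ROOT / "bundle" / "design.tsv", sep="\t")
    protein = pd.read_csv(ROOT / "protein_matrix.tsv", sep="\t", index_col=0)
    quant = pd.read_csv(ROOT / "bundle" / "peptides.tsv", sep="\t")
    retained = set((ROOT / "retained_peptides.txt").read_text().split())
    truth = SyntheticTruth.from_json(ROOT / "bundle" / "truth.json")

    bev_cols = design.loc[design["fraction"] == "bEV", "sample_id"]
    wb_cols = design.loc[design["fraction"] == "WB", "sample_id"]
    bev = protein[[c for c in bev_cols if c in protein.columns]]
    wb = protein[[c for c in wb_cols if c in protein.columns]]
    results, partition = cross_compartment_correlation(bev, wb, design)
    df = results_to_frame(results)
    df.to_csv(ROOT / "cross_compartment.tsv", sep="\t", index=False)
    neg = df[(df["significant"] == True) & (df["r"] < 0)]  # noqa: E712
    print(f"compartment partition: {len(partition['a_only'])} bEV-only, "
          f"{len(partition['b_only'])} WB-only, "
          f"{len(partition['common'])} common")
    print(f"significant negative bEV<->WB correlations: {len(neg)} "
          f"(planted anti-correlated proteins: "
          f"{sorted(truth.compartment_pairs)})")
    planted = df[df["feature_a"].isin(truth.compartment_pairs)]
    if not planted.empty:
        print(planted[["feature_a", "n", "r", "p"]].round(3).to_string(
            index=False))

    # peptide-level screen within the EV fraction, controls vs early stage
    quant = quant[quant["peptide"].isin(retained)]
    wide = quant.pivot_table(index="peptide", columns="sample_id",
                             values="count", dropna=False)
    wide = wide[[c for c in bev_cols if c in wide.columns]].astype(float)
    top = wide.mean(axis=1, skipna=True).nlargest(40).index
    table, reversals = peptide_heatmap_table(
        wide.loc[top], wide.loc[top], design, ["control", "AD3"],
        fraction="bEV",
    )
    table.to_csv(ROOT / "heatmap_table.tsv", sep="\t", index=False)
    reversals.to_csv(ROOT / "reversals.tsv", sep="\t", index=False)
    print(f"heatmap screen: {len(table)} pair-group correlations with "
          f"|r| > 0.5 in >= 1 group; {len(reversals)} sign reversals")


if __name__ == "__main__":
    main()
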