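#!/usr/bin/env python
"""Spectral-count quantification.

Zero-fills "not detected" cells, rolls unique-peptide counts up to the
protein level (exact mass balance), writes per-group mean +/- SEM
summaries, and produces the left-censored log2 matrix used by the
validation statistics path. Writes results/protein_matrix.tsv,
group_summary.tsv, log2_matrix.tsv.
"""

from pathlib import Path

import pandas as pd

from omdpipe.attribution import attribute
from omdpipe.digestion import build_peptide_index
from omdpipe.proteome_db import read_fasta
from omdpipe.quantification import (
    censored_impute_log2,
    group_summarize,
    pivot_peptides,
    rollup_to_protein,
    zero_fill,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    microbial = read_fasta(ROOT / "bundle" / "microbial.fasta")
    design = pd.read_csv(ROOT / "bundle" / "design.tsv", sep="\t")
    quant = pd.read_csv(ROOT / "bundle" / "peptides.tsv", sep="\t")
    retained = set((ROOT / "retained_peptides.txt").read_text().split())
    quant = quant[quant["peptide"].isin(retained)]

    index = build_peptide_index(microbial)
    attrib = attribute(sorted(retained), index)

    wide, n_filled = zero_fill(pivot_peptides(quant))
    protein = rollup_to_protein(wide, attrib, warn_empty=False)
    protein.to_csv(ROOT / "protein_matrix.tsv", sep="\t")
    unique = attrib.unique_to_protein()
    total_unique = wide.loc[[p for p in wide.index if p in unique]].sum().sum()
    print(f"zero-filled {n_filled} missing cells")
    print(f"protein matrix {protein.shape[0]} x {protein.shape[1]}; "
          f"mass balance residual = "
          f"{abs(protein.sum().sum() - total_unique):.0f}")

    summary = group_summarize(protein, design)
    summary.to_csv(ROOT / "group_summary.tsv", sep="\t", index=False)
    log2 = censored_impute_log2(protein)
    log2.to_csv(ROOT / "log2_matrix.tsv", sep="\t")
    print(f"group summary rows: {len(summary)}; "
          f"log2 matrix finite: {bool((log2.notna()).all().all())}")


if __name__ == "__main__":
    main()
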