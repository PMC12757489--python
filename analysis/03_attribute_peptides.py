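#!/usr/bin/env python
"""Attribute retained peptides to proteins and taxa.

Computes uniqueness flags, the common (every-subject) protein/taxon sets
with their habitat/pathogenicity/Gram breakdowns, the per-condition taxon
presence matrix, and the restricted-database consistency check. Writes
results/attribution.tsv, presence_taxon.tsv, common_sets.json.
"""

import json
from pathlib import Path

import pandas as pd

from omdpipe.attribution import (
    attribute,
    attribution_consistency_check,
    common_sets,
    presence_by_condition,
)
from omdpipe.digestion import build_peptide_index
from omdpipe.proteome_db import read_fasta, read_taxon_annotations, \
    restrict_database

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    microbial = read_fasta(ROOT / "bundle" / "microbial.fasta")
    annotations = read_taxon_annotations(
        ROOT / "bundle" / "annotations.tsv", known_taxa=microbial.taxa
    )
    design = pd.read_csv(ROOT / "bundle" / "design.tsv", sep="\t")
    quant = pd.read_csv(ROOT / "bundle" / "peptides.tsv", sep="\t")
    retained = (ROOT / "retained_peptides.txt").read_text().split()
    quant = quant[quant["peptide"].isin(set(retained))]

    index = build_peptide_index(microbial)
    attrib = attribute(retained, index, annotations)
    attrib.to_tsv(ROOT / "attribution.tsv")
    n_unique = len(attrib.unique_to_protein())
    print(f"attributed {len(attrib.peptides)} peptides "
          f"({n_unique} unique to a single protein, "
          f"{len(attrib.orphans)} orphans)")

    summary = common_sets(attrib, design, quant, annotations)
    with open(ROOT / "common_sets.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    print(f"common proteins: {summary['proteins']['n_common']}/"
          f"{summary['proteins']['n_detected']} "
          f"({100 * summary['proteins']['fraction_common']:.0f}%); "
          f"common taxa: {summary['taxa']['n_common']}/"
          f"{summary['taxa']['n_detected']}")
    print("  common-taxa Gram breakdown:",
          summary["taxa"].get("common_by_gram"))

    presence = presence_by_condition(attrib, quant, design)
    presence.to_csv(ROOT / "presence_taxon.tsv", sep="\t")
    print(f"presence matrix: {presence.shape[0]} taxa x "
          f"{presence.shape[1]} conditions")

    identified = {
        acc for pep in attrib.peptides["peptide"]
        for acc in index.proteins(pep)
    }
    restricted = build_peptide_index(
        restrict_database(microbial, identified)
    )
    report = attribution_consistency_check(
        list(attrib.peptides["peptide"]), index, restricted
    )
    print(f"restricted-database check: consistent={report.consistent}; "
          f"{len(report.gained_uniqueness)} peptides gained uniqueness, "
          f"{report.unique_before} -> {report.unique_after} unique")


if __name__ == "__main__":
    main()
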