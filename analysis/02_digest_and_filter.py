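#!/usr/bin/env python
"""Digest the microbial database and remove host-ambiguous peptides.

Builds the tryptic peptide index (7-22 residues, up to 2 missed cleavages)
and excludes every observed peptide whose I/L variants occur anywhere in
the host proteome — the screen that protects the microbial attribution
from host contamination. Writes results/filter_report.tsv.
"""

from pathlib import Path

import pandas as pd

from omdpipe.digestion import build_peptide_index, export_index_tsv
from omdpipe.host_filter import filter_host_homologs
from omdpipe.proteome_db import read_fasta

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    microbial = read_fasta(ROOT / "bundle" / "microbial.fasta")
    host = read_fasta(ROOT / "bundle" / "host.fasta", kind="host")
    quant = pd.read_csv(ROOT / "bundle" / "peptides.tsv", sep="\t")

    index = build_peptide_index(microbial)
    export_index_tsv(index, ROOT / "peptide_index.tsv")
    print(f"indexed {len(index)} peptides from {len(microbial)} proteins")

    observed = list(dict.fromkeys(quant["peptide"]))
    retained, report = filter_host_homologs(observed, host)
    report.to_tsv(ROOT / "filter_report.tsv")
    (ROOT / "retained_peptides.txt").write_text("\n".join(retained) + "\n")
    print(f"host filter: {report.n_retained}/{report.n_input} retained, "
          f"{report.n_excluded} excluded")
    reasons = pd.Series([d.reason for d in report.decisions if d.excluded])
    print("  exclusion reasons:", reasons.value_counts().to_dict())


if __name__ == "__main__":
    main()
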