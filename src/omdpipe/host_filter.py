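"""Host-homology exclusion of candidate microbial peptides.

Mass spectrometry cannot distinguish isoleucine from leucine, so a peptide
attributed to a microbial database entry must be discarded if *any* of its
2^k I/L variants (k = number of I/L residues) occurs in the host proteome:
otherwise the spectrum could equally well come from a host protein.

Enumerating 2^k variants is exponential; the production path instead
canonicalizes I->L on both the peptide and the host sequences and performs a
single substring search, which is exactly equivalent to variant enumeration
(two sequences have a common I/L variant iff their canonical forms are
equal). The explicit enumeration is retained in :func:`il_variants` and
serves as the independent test oracle.

Two matching modes are provided: ``substring`` (default; occurrence anywhere
in a host sequence — the conservative reading of "present in the host
proteome") and ``tryptic`` (match against the host's own tryptic peptides,
for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

from .digestion import build_peptide_index
from .proteome_db import ProteinDatabase


def canonicalize_il(sequence: str) -> str:
    """Collapse the I/L ambiguity class: replace every I with L."""
    return sequence.replace("I", "L")


def il_variants(sequence: str) -> set[str]:
    """All 2^k isoleucine/leucine variants of a peptide (input included)."""
    positions = [i for i, c in enumerate(sequence) if c in "IL"]
    chars = list(sequence)
    variants: set[str] = set()
    for combo in product("IL", repeat=len(positions)):
        for pos, c in zip(positions, combo):
            chars[pos] = c
        variants.add("".join(chars))
    return variants


@dataclass
class FilterDecision:
    peptide: str
    excluded: bool
    reason: str = ""  # "host_match" | "ambiguous residue" | ""
    n_variants: int = 1
    host_accessions: tuple[str, ...] = ()


@dataclass
class FilterReport:
    mode: str
    decisions: list[FilterDecision] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.decisions)

    @property
    def n_excluded(self) -> int:
        return sum(d.excluded for d in self.decisions)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("peptide\tdecision\treason\tn_variants\thost_accessions\n")
            for d in self.decisions:
                fh.write(
                    f"{d.peptide}\t{'excluded' if d.excluded else 'retained'}\t"
                    f"{d.reason}\t{d.n_variants}\t{';'.join(d.host_accessions)}\n"
                )


class HostMatcher:
    """Reusable I/L-canonical matcher over one host database."""

    def __init__(
        self,
        host: ProteinDatabase,
        mode: str = "substring",
        max_missed: int = 2,
        min_len: int = 1,
        max_len: int = 10**6,
    ):
        if len(host) == 0:
            raise ValueError("host database is empty; filter would be vacuous")
        if mode not in ("substring", "tryptic"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        if mode == "substring":
            self._canon_seqs = [
                (rec.accession, canonicalize_il(rec.sequence)) for rec in host
            ]
            # single concatenated text for the fast yes/no test
            self._haystack = "#".join(s for _, s in self._canon_seqs)
        else:
            index = build_peptide_index(
                host, max_missed=max_missed, min_len=min_len, max_len=max_len
            )
            self._tryptic: dict[str, tuple[str, ...]] = {}
            for seq, parents in index.items():
                canon = canonicalize_il(seq)
                accs = tuple(sorted({p.accession for p in parents}))
                prev = self._tryptic.get(canon, ())
                self._tryptic[canon] = tuple(sorted(set(prev) | set(accs)))

    def matches(self, peptide: str) -> tuple[str, ...]:
        """Host accessions containing an I/L variant of ``peptide``."""
        canon = canonicalize_il(peptide.upper())
        if self.mode == "substring":
            if canon not in self._haystack:
                return ()
            return tuple(
                acc for acc, seq in self._canon_seqs if canon in seq
            )
        return self._tryptic.get(canon, ())


def filter_host_homologs(
    peptides: Sequence[str] | Iterable[str],
    host: ProteinDatabase,
    mode: str = "substring",
) -> tuple[list[str], FilterReport]:
    """Split candidate peptides into retained and host-excluded.

    A peptide is excluded iff any of its I/L variants occurs in the host
    (per the selected mode). Peptides containing ``X`` are excluded with
    reason ``ambiguous residue``. Input order is preserved in the retained
    list; the report covers every input peptide.
    """
    matcher = HostMatcher(host, mode=mode)
    retained: list[str] = []
    report = FilterReport(mode=mode)
    for pep in peptides:
        pep = pep.upper()
        k = sum(1 for c in pep if c in "IL")
        if "X" in pep:
            report.decisions.append(
                FilterDecision(pep, True, "ambiguous residue", 2**k)
            )
            continue
        hits = matcher.matches(pep)
        if hits:
            report.decisions.append(
                FilterDecision(pep, True, "host_match", 2**k, hits)
            )
        else:
            report.decisions.append(FilterDecision(pep, False, "", 2**k))
            retained.append(pep)
    return retained, report


def brute_force_host_match(peptide: str, host: ProteinDatabase) -> tuple[str, ...]:
    """Test oracle: literally enumerate the 2^k variants and scan every
    host sequence for each one. Independent of the canonical fast path.
    """
    hits = []
    variants = il_variants(peptide.upper())
    for rec in host:
        if any(variant in rec.sequence for variant in variants):
            hits.append(rec.accession)
    return tuple(hits)


__all__ = [
    "canonicalize_il",
    "il_variants",
    "FilterDecision",
    "FilterReport",
    "HostMatcher",
    "filter_host_homologs",
    "brute_force_host_match",
]
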