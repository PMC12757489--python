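"""In-silico tryptic digestion and the peptide-to-parent index.

Cleavage follows the classic trypsin rule — after K or R, suppressed when
the next residue is proline — applied via :func:`pyteomics.parser.xcleave`
so fragment start offsets are tracked. Identified peptides in the emulated
experiments fall in a 7–22 residue window, which is the default length
filter here.

I and L are *not* merged at digestion/index time: attribution stays literal
to the database sequences, and I/L ambiguity is handled exclusively by the
host-homology filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyteomics import parser as _parser

from .proteome_db import ProteinDatabase, ProteinRecord

#: cleave after K or R unless followed by P (no further exceptions)
TRYPSIN_RULE = r"[KR](?=[^P])"

DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 22
DEFAULT_MAX_MISSED = 2


@dataclass(frozen=True)
class Parent:
    """One occurrence of a peptide inside a protein."""

    accession: str
    taxon_id: str
    offset: int  # 0-based start of the peptide in the parent sequence


@dataclass
class Peptide:
    sequence: str
    missed_cleavages: int
    parents: list[Parent] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def digest(
    protein: ProteinRecord,
    max_missed: int = DEFAULT_MAX_MISSED,
) -> list[Peptide]:
    """Tryptic fragments of one protein with 0..max_missed missed cleavages.

    Duplicated sequences within the protein are retained as distinct
    offsets. No length filter is applied here.
    """
    out: list[Peptide] = []
    for start, frag in _parser.xcleave(
        protein.sequence, TRYPSIN_RULE, missed_cleavages=max_missed, min_length=1
    ):
        # xcleave does not report the number of missed cleavages; recount
        # internal cleavage sites (K/R not before P, excluding the C-term).
        missed = sum(
            1
            for i in range(len(frag) - 1)
            if frag[i] in "KR" and frag[i + 1] != "P"
        )
        out.append(
            Peptide(
                sequence=frag,
                missed_cleavages=missed,
                parents=[Parent(protein.accession, protein.taxon_id, start)],
            )
        )
    out.sort(key=lambda p: (p.parents[0].offset, p.length))
    return out


def length_filter(
    peptides: Iterable[Peptide],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Peptide]:
    if not (0 < min_len <= max_len):
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    return [p for p in peptides if min_len <= p.length <= max_len]


class PeptideIndex:
    """Map peptide sequence -> every (protein, taxon, offset) parent.

    Built over a whole database; equal sequences arising from different
    proteins (or different positions in one protein) are merged into one
    entry. Peptides containing ``X`` (sanitized non-canonical residues) are
    excluded: they cannot be compared unambiguously under I/L-variant logic.
    """

    def __init__(self, entries: Mapping[str, list[Parent]]):
        self._entries: dict[str, list[Parent]] = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._entries

    def __iter__(self):
        return iter(self._entries)

    def parents(self, sequence: str) -> list[Parent]:
        return self._entries[sequence]

    def proteins(self, sequence: str) -> set[str]:
        return {p.accession for p in self._entries[sequence]}

    def taxa(self, sequence: str) -> set[str]:
        return {p.taxon_id for p in self._entries[sequence]}

    @property
    def sequences(self) -> list[str]:
        return sorted(self._entries)

    def items(self):
        return self._entries.items()


def build_peptide_index(
    db: ProteinDatabase,
    max_missed: int = DEFAULT_MAX_MISSED,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> PeptideIndex:
    """Digest every protein and merge equal sequences across the database."""
    if len(db) == 0:
        raise ValueError("cannot index an empty database")
    entries: dict[str, list[Parent]] = {}
    for protein in db:
        for pep in length_filter(digest(protein, max_missed), min_len, max_len):
            if "X" in pep.sequence:
                continue
            entries.setdefault(pep.sequence, []).extend(pep.parents)
    return PeptideIndex(entries)


def export_index_tsv(index: PeptideIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tn_parents\tparents\n")
        for seq in index.sequences:
            parents = index.parents(seq)
            spec = ";".join(
                f"{p.accession}@{p.offset}({p.taxon_id})" for p in parents
            )
            fh.write(f"{seq}\t{len(parents)}\t{spec}\n")


__all__ = [
    "TRYPSIN_RULE",
    "Parent",
    "Peptide",
    "digest",
    "length_filter",
    "PeptideIndex",
    "build_peptide_index",
    "export_index_tsv",
]
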