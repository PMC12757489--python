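"""Protein database model and I/O.

A :class:`ProteinDatabase` holds the search space for peptide attribution:
either a multi-taxon microbial database (every record linked to the taxon
that produced it, mirroring how oral-microbiome reference databases embed
the species in each entry name) or a host proteome (records carry the
``HOST`` sentinel taxon). Taxon-level metadata — habitat, pathogenicity and
Gram status — live in a separate annotation table keyed by taxon id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

HOST_TAXON = "HOST"

#: the 20 canonical residues; everything else is sanitized to "X"
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

HABITATS = {"oral", "gut", "other", "unannotated"}
PATHOGENICITIES = {
    "disease_associated",
    "opportunistic",
    "health_associated",
    "unannotated",
}
GRAM_STATUSES = {"negative", "positive", "not_applicable", "unannotated"}

#: default header dialect: ``>accession|taxon|gene_symbol description``
DEFAULT_HEADER_PATTERN = (
    r"^(?P<accession>[^|\s]+)\|(?P<taxon>[^|\s]+)\|(?P<symbol>[^|\s]+)"
    r"(?:\s+(?P<description>.*))?$"
)


class DatabaseError(ValueError):
    """Malformed database input (header, duplicate accession, bad enum)."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    taxon_id: str
    gene_symbol: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"record {self.accession!r}: empty sequence")

    @property
    def is_host(self) -> bool:
        return self.taxon_id == HOST_TAXON


@dataclass(frozen=True)
class TaxonAnnotation:
    taxon_id: str
    habitat: str = "unannotated"
    pathogenicity: str = "unannotated"
    gram: str = "unannotated"

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise DatabaseError(f"unknown habitat token {self.habitat!r}")
        if self.pathogenicity not in PATHOGENICITIES:
            raise DatabaseError(
                f"unknown pathogenicity token {self.pathogenicity!r}"
            )
        if self.gram not in GRAM_STATUSES:
            raise DatabaseError(f"unknown gram token {self.gram!r}")


@dataclass
class ProteinDatabase:
    """Ordered collection of protein records with unique accessions."""

    records: list[ProteinRecord] = field(default_factory=list)
    kind: str = "microbial"  # or "host"

    def __post_init__(self) -> None:
        self._by_accession: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self._by_accession:
                raise DatabaseError(f"duplicated accession {rec.accession!r}")
            self._by_accession[rec.accession] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def get(self, accession: str) -> ProteinRecord:
        return self._by_accession[accession]

    @property
    def taxa(self) -> set[str]:
        return {r.taxon_id for r in self.records}

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]


def sanitize_sequence(seq: str) -> str:
    """Uppercase, strip whitespace, map non-canonical residues to ``X``."""
    seq = "".join(seq.split()).upper()
    return "".join(c if c in CANONICAL_AA else "X" for c in seq)


def read_fasta(
    path: str | Path,
    kind: str = "microbial",
    header_pattern: str = DEFAULT_HEADER_PATTERN,
) -> ProteinDatabase:
    """Read a FASTA protein database.

    Headers are parsed with a configurable regular expression using named
    groups ``accession``, ``taxon``, ``symbol`` and optional ``description``
    (default dialect ``acc|taxon|symbol``). Host databases ignore the taxon
    token and take the ``HOST`` sentinel; if the header has no ``|`` fields
    the whole first word is used as accession.
    """
    pattern = re.compile(header_pattern)
    records: list[ProteinRecord] = []
    for ordinal, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        m = pattern.match(header)
        if m is None:
            if kind == "host":
                # plain headers are fine for a host proteome
                accession, taxon, symbol, desc = rec.id, HOST_TAXON, "", ""
            else:
                raise DatabaseError(
                    f"record #{ordinal}: malformed header {header!r}"
                )
        else:
            accession = m.group("accession")
            taxon = m.group("taxon")
            symbol = m.group("symbol") or ""
            desc = (m.groupdict().get("description") or "") or ""
        if kind == "host":
            taxon = HOST_TAXON
        seq = sanitize_sequence(str(rec.seq))
        if not seq:
            raise DatabaseError(f"record #{ordinal} ({accession!r}): empty sequence")
        records.append(
            ProteinRecord(
                accession=accession,
                sequence=seq,
                taxon_id=taxon,
                gene_symbol=symbol,
                description=desc,
            )
        )
    return ProteinDatabase(records=records, kind=kind)


def write_fasta(db: ProteinDatabase, path: str | Path, width: int = 60) -> None:
    """Write the database in the ``acc|taxon|symbol`` header dialect."""
    seq_records = []
    for rec in db:
        header = f"{rec.accession}|{rec.taxon_id}|{rec.gene_symbol or '-'}"
        if rec.description:
            header += f" {rec.description}"
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=header, description="")
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_taxon_annotations(
    path: str | Path,
    known_taxa: Iterable[str] | None = None,
) -> dict[str, TaxonAnnotation]:
    """Read the 4-column taxon annotation TSV (header row required).

    Taxa present in ``known_taxa`` but absent from the table are given
    explicit ``unannotated`` placeholders with a logged warning — they are
    never silently dropped.
    """
    annotations: dict[str, TaxonAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["taxon_id", "habitat", "pathogenicity", "gram"]
        if [h.strip() for h in header] != expected:
            raise DatabaseError(
                f"annotation header {header!r} != expected {expected!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise DatabaseError(f"row {lineno}: expected 4 columns")
            taxon, habitat, patho, gram = (p.strip() for p in parts)
            try:
                annotations[taxon] = TaxonAnnotation(taxon, habitat, patho, gram)
            except DatabaseError as exc:
                raise DatabaseError(f"row {lineno}: {exc}") from exc
    if known_taxa is not None:
        for taxon in known_taxa:
            if taxon not in annotations and taxon != HOST_TAXON:
                logger.warning(
                    "taxon %s has no annotation row; recording as unannotated",
                    taxon,
                )
                annotations[taxon] = TaxonAnnotation(taxon)
    return annotations


def write_taxon_annotations(
    annotations: Mapping[str, TaxonAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_id\thabitat\tpathogenicity\tgram\n")
        for taxon in sorted(annotations):
            a = annotations[taxon]
            fh.write(f"{a.taxon_id}\t{a.habitat}\t{a.pathogenicity}\t{a.gram}\n")


def restrict_database(
    db: ProteinDatabase, keep: Iterable[str]
) -> ProteinDatabase:
    """Subset a database to records whose taxon or accession is in ``keep``.

    This is the database-reduction step used by the attribution-consistency
    check: after a first pass identifies taxa/proteins, re-attribution is run
    against only those entries and compared with the full-database result.
    """
    keep_set = set(keep)
    if not keep_set:
        raise DatabaseError("keep set is empty")
    kept = [
        rec
        for rec in db
        if rec.taxon_id in keep_set or rec.accession in keep_set
    ]
    if not kept:
        raise DatabaseError("keep set is disjoint from the database")
    return ProteinDatabase(records=list(kept), kind=db.kind)


__all__ = [
    "HOST_TAXON",
    "CANONICAL_AA",
    "DatabaseError",
    "ProteinRecord",
    "TaxonAnnotation",
    "ProteinDatabase",
    "DEFAULT_HEADER_PATTERN",
    "sanitize_sequence",
    "read_fasta",
    "write_fasta",
    "read_taxon_annotations",
    "write_taxon_annotations",
    "restrict_database",
]
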