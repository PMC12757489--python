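"""Peptide-to-protein/taxon attribution and presence summaries.

Uniqueness drives everything downstream: a peptide unique to a single
protein is the only admissible evidence for that protein's quantification,
and a peptide whose parents all belong to one taxon is the evidence used to
call that organism present in a condition. Commonality summaries (the
fraction of proteins/taxa detected in *every* subject) and the
database-restriction consistency check are computed here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .digestion import PeptideIndex
from .proteome_db import TaxonAnnotation


@dataclass
class AttributionTable:
    """Per-peptide parent sets and uniqueness flags, plus roll-ups."""

    peptides: pd.DataFrame  # peptide, proteins, taxa, unique_to_protein, unique_to_taxon
    orphans: list[str] = field(default_factory=list)

    def unique_to_protein(self) -> set[str]:
        df = self.peptides
        return set(df.loc[df["unique_to_protein"], "peptide"])

    def unique_to_taxon(self) -> set[str]:
        df = self.peptides
        return set(df.loc[df["unique_to_taxon"], "peptide"])

    def protein_of(self, peptide: str) -> str:
        row = self.peptides.set_index("peptide").loc[peptide]
        return row["proteins"][0]

    def to_tsv(self, path) -> None:
        df = self.peptides.copy()
        df["proteins"] = df["proteins"].map(";".join)
        df["taxa"] = df["taxa"].map(";".join)
        df.to_csv(path, sep="\t", index=False)


def attribute(
    peptides: Iterable[str],
    index: PeptideIndex,
    annotations: Mapping[str, TaxonAnnotation] | None = None,
) -> AttributionTable:
    """Resolve retained peptides against the database index.

    Peptides absent from the index are collected in the ``orphans`` list —
    reported, never silently dropped. Annotation columns (habitat,
    pathogenicity, Gram) are joined when the peptide is unique to a taxon.
    """
    rows = []
    orphans: list[str] = []
    for pep in peptides:
        if pep not in index:
            orphans.append(pep)
            continue
        proteins = sorted(index.proteins(pep))
        taxa = sorted(index.taxa(pep))
        unique_protein = len(proteins) == 1
        unique_taxon = len(taxa) == 1
        row = {
            "peptide": pep,
            "proteins": proteins,
            "taxa": taxa,
            "unique_to_protein": unique_protein,
            "unique_to_taxon": unique_taxon,
        }
        if annotations is not None and unique_taxon:
            ann = annotations.get(taxa[0])
            row["habitat"] = ann.habitat if ann else "unannotated"
            row["pathogenicity"] = ann.pathogenicity if ann else "unannotated"
            row["gram"] = ann.gram if ann else "unannotated"
        rows.append(row)
    columns = ["peptide", "proteins", "taxa", "unique_to_protein", "unique_to_taxon"]
    if annotations is not None:
        columns += ["habitat", "pathogenicity", "gram"]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=columns)
    return AttributionTable(peptides=df, orphans=orphans)


def _detected_long(quant: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Join counts with design; keep rows with a positive count."""
    quant_samples = set(quant["sample_id"].unique())
    design_samples = set(design["sample_id"])
    extra = quant_samples - design_samples
    if extra:
        raise ValueError(
            f"quant table has samples missing from the design: {sorted(extra)[:5]}"
        )
    merged = quant.merge(design, on="sample_id", how="inner")
    return merged[merged["count"].fillna(0) > 0]


def common_sets(
    attrib: AttributionTable,
    design: pd.DataFrame,
    quant: pd.DataFrame,
    annotations: Mapping[str, TaxonAnnotation] | None = None,
) -> dict:
    """Proteins/taxa detected in every subject ("common") vs the rest.

    Detection in a subject pools that subject's technical replicates and
    fractions: any supporting peptide with count > 0 in any of the subject's
    samples counts. Supporting evidence is unique-to-protein peptides for
    proteins and unique-to-taxon peptides for taxa. Returns counts,
    fractions, and habitat/pathogenicity/Gram breakdowns of the common taxa.
    """
    detected = _detected_long(quant, design)
    n_subjects = design["subject_id"].nunique()
    pep_meta = attrib.peptides.set_index("peptide")

    def _common(feature_of: dict[str, list[str]]) -> tuple[set[str], set[str]]:
        subj_sets: dict[str, set[str]] = {}
        for row in detected.itertuples():
            for feat in feature_of.get(row.peptide, ()):
                subj_sets.setdefault(feat, set()).add(row.subject_id)
        all_feats = set(subj_sets)
        common = {f for f, s in subj_sets.items() if len(s) == n_subjects}
        return common, all_feats

    prot_of = {
        pep: list(meta["proteins"])
        for pep, meta in pep_meta.iterrows()
        if meta["unique_to_protein"]
    }
    taxon_of = {
        pep: list(meta["taxa"])
        for pep, meta in pep_meta.iterrows()
        if meta["unique_to_taxon"]
    }
    common_prot, all_prot = _common(prot_of)
    common_taxa, all_taxa = _common(taxon_of)

    summary = {
        "n_subjects": int(n_subjects),
        "proteins": {
            "n_detected": len(all_prot),
            "n_common": len(common_prot),
            "fraction_common": len(common_prot) / len(all_prot) if all_prot else 0.0,
            "common": sorted(common_prot),
        },
        "taxa": {
            "n_detected": len(all_taxa),
            "n_common": len(common_taxa),
            "fraction_common": len(common_taxa) / len(all_taxa) if all_taxa else 0.0,
            "common": sorted(common_taxa),
        },
    }
    if annotations is not None:
        for key in ("habitat", "pathogenicity", "gram"):
            breakdown: dict[str, int] = {}
            for taxon in common_taxa:
                ann = annotations.get(taxon)
                value = getattr(ann, key) if ann else "unannotated"
                breakdown[value] = breakdown.get(value, 0) + 1
            summary["taxa"][f"common_by_{key}"] = breakdown
    return summary


def presence_by_condition(
    attrib: AttributionTable,
    quant: pd.DataFrame,
    design: pd.DataFrame,
    level: str = "taxon",
) -> pd.DataFrame:
    """Presence matrix: rows = taxa (or proteins), columns = conditions.

    A taxon is present in a condition iff at least one of its
    unique-to-taxon peptides has a positive count in at least one sample of
    that condition (protein-level mode uses unique-to-protein peptides).
    """
    if level not in ("taxon", "protein"):
        raise ValueError(f"unknown level {level!r}")
    detected = _detected_long(quant, design)
    pep_meta = attrib.peptides.set_index("peptide")
    flag = "unique_to_taxon" if level == "taxon" else "unique_to_protein"
    col = "taxa" if level == "taxon" else "proteins"
    feature_of = {
        pep: meta[col][0]
        for pep, meta in pep_meta.iterrows()
        if meta[flag]
    }
    groups = list(dict.fromkeys(design["group"]))
    features = sorted(set(feature_of.values()))
    presence = pd.DataFrame(False, index=features, columns=groups)
    for row in detected.itertuples():
        feat = feature_of.get(row.peptide)
        if feat is not None:
            presence.loc[feat, row.group] = True
    presence.index.name = level
    return presence


@dataclass
class ConsistencyReport:
    """Outcome of re-attribution against a restricted database."""

    n_peptides: int
    gained_uniqueness: list[str]
    lost_parents: list[str]  # must be empty when restriction keeps parents
    unique_before: int
    unique_after: int

    @property
    def consistent(self) -> bool:
        return not self.lost_parents and self.unique_after >= self.unique_before


def attribution_consistency_check(
    peptides: Iterable[str],
    full_index: PeptideIndex,
    restricted_index: PeptideIndex,
) -> ConsistencyReport:
    """Compare attribution under the full vs restricted database.

    Restriction can only shrink parent sets, so peptides may gain
    protein-level uniqueness (shared -> unique) but never lose it; a peptide
    losing *all* parents indicates the restriction dropped an identified
    protein and is reported as an inconsistency.
    """
    gained, lost = [], []
    unique_before = unique_after = 0
    n = 0
    for pep in peptides:
        n += 1
        before = full_index.proteins(pep) if pep in full_index else set()
        after = (
            restricted_index.proteins(pep) if pep in restricted_index else set()
        )
        if not after <= before:
            raise AssertionError(
                f"parent set grew under restriction for {pep!r}"
            )
        if before and not after:
            lost.append(pep)
            continue
        if len(before) == 1:
            unique_before += 1
        if len(after) == 1:
            unique_after += 1
            if len(before) > 1:
                gained.append(pep)
    return ConsistencyReport(
        n_peptides=n,
        gained_uniqueness=sorted(gained),
        lost_parents=sorted(lost),
        unique_before=unique_before,
        unique_after=unique_after,
    )


__all__ = [
    "AttributionTable",
    "attribute",
    "common_sets",
    "presence_by_condition",
    "ConsistencyReport",
    "attribution_consistency_check",
]
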