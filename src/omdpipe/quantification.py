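"""Spectral-count quantification.

Protein abundance is proxied by the total number of MS/MS spectra assigned
to that protein's peptides, restricted to peptides unambiguously assigned
to a single protein so counts are never cross-attributed between taxa.
Two missing-value policies are provided, mirroring the primary and
validation analysis paths of the emulated study:

* zero-fill — "not detected" cells become 0 before roll-up (primary path);
* left-censored imputation + log2 — zeros/missing replaced near the
  detection limit, then log2-transformed (validation path). The default
  imputation is the deterministic half-minimum of the protein's positive
  values; a stochastic down-shifted Gaussian draw in log2 space is
  available behind a seed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .attribution import AttributionTable

logger = logging.getLogger(__name__)


def pivot_peptides(quant: pd.DataFrame) -> pd.DataFrame:
    """Long-form (peptide, sample_id, count) -> wide peptide x sample.

    Cells that were never observed, or observed only as "not detected",
    stay missing — zero-filling is a separate, explicit policy step.
    """
    wide = quant.pivot_table(
        index="peptide", columns="sample_id", values="count",
        aggfunc=lambda s: s.sum(min_count=1), dropna=False,
    )
    wide.columns.name = None
    return wide


def zero_fill(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Replace missing cells with 0; returns (table, number filled)."""
    n_missing = int(table.isna().sum().sum())
    filled = table.fillna(0.0)
    if n_missing:
        logger.info("zero-filled %d missing cells", n_missing)
    return filled, n_missing


def rollup_to_protein(
    peptide_matrix: pd.DataFrame,
    attrib: AttributionTable,
    warn_empty: bool = True,
) -> pd.DataFrame:
    """Protein x sample matrix from unique-peptide counts.

    Only unique-to-protein peptides contribute; each protein's value is the
    sum of its unique peptides' counts in that sample (exact conservation).
    Proteins attributed only through shared peptides appear with an
    all-zero row and a warning.
    """
    if peptide_matrix.isna().any().any():
        raise ValueError("apply zero_fill before protein roll-up")
    pep_meta = attrib.peptides.set_index("peptide")
    all_proteins = sorted(
        {acc for plist in pep_meta["proteins"] for acc in plist}
    )
    rows = np.zeros((len(all_proteins), peptide_matrix.shape[1]))
    pos = {acc: i for i, acc in enumerate(all_proteins)}
    contributing: set[str] = set()
    for pep in peptide_matrix.index:
        if pep not in pep_meta.index:
            continue
        meta = pep_meta.loc[pep]
        if not meta["unique_to_protein"]:
            continue
        acc = meta["proteins"][0]
        rows[pos[acc]] += peptide_matrix.loc[pep].to_numpy(dtype=float)
        contributing.add(acc)
    empty = set(all_proteins) - contributing
    if empty and warn_empty:
        logger.warning(
            "%d proteins have no unique peptides (all-zero rows)", len(empty)
        )
    return pd.DataFrame(
        rows, index=all_proteins, columns=peptide_matrix.columns
    )


def average_replicates(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Average technical replicates within each subject (columns become
    subject ids), so downstream group statistics see n = subjects."""
    design = design[design["sample_id"].isin(matrix.columns)]
    subj = design.set_index("sample_id")["subject_id"]
    return matrix.T.groupby(subj).mean().T


def group_summarize(
    protein_matrix: pd.DataFrame,
    design: pd.DataFrame,
    pool_replicates: bool = False,
) -> pd.DataFrame:
    """Per-protein, per-group mean and SEM (long form).

    Technical replicates are averaged within subject first, so n per group
    equals the number of subjects; ``pool_replicates=True`` instead treats
    every run as an observation. Groups with a single observation get a
    missing SEM.
    """
    design = design[design["sample_id"].isin(protein_matrix.columns)]
    if pool_replicates:
        values = protein_matrix
        unit_group = design.set_index("sample_id")["group"]
    else:
        values = average_replicates(protein_matrix, design)
        unit_group = (
            design.drop_duplicates("subject_id")
            .set_index("subject_id")["group"]
        )
    records = []
    for group, cols in unit_group.groupby(unit_group).groups.items():
        sub = values[list(cols)]
        n = sub.shape[1]
        mean = sub.mean(axis=1)
        sem = sub.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(
            np.nan, index=sub.index
        )
        for acc in sub.index:
            records.append(
                {
                    "protein": acc,
                    "group": group,
                    "mean": float(mean[acc]),
                    "sem": float(sem[acc]) if n > 1 else np.nan,
                    "n": int(n),
                }
            )
    return pd.DataFrame(records)


def group_mean_matrix(
    protein_matrix: pd.DataFrame,
    design: pd.DataFrame,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Protein x group matrix of means (replicates averaged per subject)."""
    summary = group_summarize(protein_matrix, design)
    mat = summary.pivot(index="protein", columns="group", values="mean")
    if groups is not None:
        mat = mat[groups]
    mat.columns.name = None
    return mat


def censored_impute_log2(
    matrix: pd.DataFrame,
    policy: str = "half_min",
    seed: int = 0,
    shift: float = 1.8,
    width: float = 0.3,
) -> pd.DataFrame:
    """Left-censored imputation followed by log2 transform.

    ``half_min``: zeros/missing in a row become half that row's minimum
    positive value (deterministic default). ``downshift``: draws from a
    Gaussian centered ``shift`` row-SDs below the row mean in log2 space
    with ``width`` row-SDs, seeded. Rows with no positive value are imputed
    at half the global minimum positive value and flagged via a warning.
    """
    if (matrix.fillna(0) < 0).any().any():
        raise ValueError("matrix must be non-negative")
    if policy not in ("half_min", "downshift"):
        raise ValueError(f"unknown imputation policy {policy!r}")
    values = matrix.to_numpy(dtype=float).copy()
    values[np.isnan(values)] = 0.0
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive entries to anchor imputation")
    global_floor = positive.min() / 2.0
    rng = np.random.default_rng(seed)
    out = np.empty_like(values)
    n_allzero = 0
    for i in range(values.shape[0]):
        row = values[i]
        pos = row[row > 0]
        if pos.size == 0:
            n_allzero += 1
            out[i] = np.log2(global_floor)
            continue
        if policy == "half_min":
            imputed = pos.min() / 2.0
            filled = np.where(row > 0, row, imputed)
            out[i] = np.log2(filled)
        else:
            log_pos = np.log2(pos)
            mu = log_pos.mean() - shift * (log_pos.std(ddof=0) or 1.0)
            sd = width * (log_pos.std(ddof=0) or 1.0)
            draws = rng.normal(mu, sd, size=row.size)
            out[i] = np.where(row > 0, np.log2(np.where(row > 0, row, 1.0)), draws)
    if n_allzero:
        logger.warning("%d all-zero rows imputed at the global floor", n_allzero)
    result = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    if not np.isfinite(result.to_numpy()).all():
        raise AssertionError("imputed matrix contains non-finite values")
    return result


__all__ = [
    "pivot_peptides",
    "zero_fill",
    "rollup_to_protein",
    "average_replicates",
    "group_summarize",
    "group_mean_matrix",
    "censored_impute_log2",
]
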