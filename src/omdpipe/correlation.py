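"""Correlation screens.

Pearson correlations within study groups, with the strength conventions of
the emulated study: strong when |r| >= 0.70, very strong when |r| >= 0.85,
significance at p <= 0.05, 95% confidence intervals by Fisher's z. Three
screens are provided: generic feature-pair correlations, the peptidome-wide
heatmap table against marker peptides (with detection of correlations that
reverse sign between groups), and the cross-compartment screen relating
each common protein's levels in EVs to its levels in the paired tissue
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STRONG_R = 0.70
VERY_STRONG_R = 0.85
HEATMAP_MIN_R = 0.5


def strength_tier(r: float) -> str:
    if abs(r) >= VERY_STRONG_R:
        return "very_strong"
    if abs(r) >= STRONG_R:
        return "strong"
    return "none"


def fisher_ci(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Confidence interval for Pearson r via the Fisher z transform."""
    if n <= 3 or abs(r) >= 1.0:
        return (-1.0, 1.0) if abs(r) < 1.0 else (r, r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + confidence / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


@dataclass
class CorrelationResult:
    feature_a: str
    feature_b: str
    group: str
    n: int
    r: float
    ci_low: float
    ci_high: float
    p: float
    tier: str
    significant: bool
    flag: str = ""  # "zero_variance" | "too_few" | ""


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return np.nan, np.nan, "too_few"
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, "zero_variance"
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), ""


def _result(a: str, b: str, group: str, x: np.ndarray, y: np.ndarray,
            alpha: float = 0.05) -> CorrelationResult:
    r, p, flag = _pearson(x, y)
    n = int(np.sum(np.isfinite(x) & np.isfinite(y)))
    if flag:
        return CorrelationResult(a, b, group, n, np.nan, np.nan, np.nan,
                                 np.nan, "none", False, flag)
    lo, hi = fisher_ci(r, n)
    return CorrelationResult(
        a, b, group, n, r, lo, hi, p, strength_tier(r), p <= alpha
    )


def results_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    cols = ["feature_a", "feature_b", "group", "n", "r", "ci_low", "ci_high",
            "p", "tier", "significant", "flag"]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def _group_samples(design: pd.DataFrame, group: str,
                   fraction: str | None = None) -> list[str]:
    sel = design["group"] == group
    if fraction is not None:
        sel &= design["fraction"] == fraction
    return design.loc[sel, "sample_id"].tolist()


def correlate_pairs(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    design: pd.DataFrame,
    group: str,
    fraction: str | None = None,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Pearson r for every (row of A, row of B) pair over the group's
    shared samples. Pairs with zero variance or fewer than 3 complete
    observations are reported with a flag rather than dropped."""
    if group not in set(design["group"]):
        raise ValueError(f"group {group!r} absent from design")
    samples = [
        s for s in _group_samples(design, group, fraction)
        if s in matrix_a.columns and s in matrix_b.columns
    ]
    out = []
    for a in matrix_a.index:
        xa = matrix_a.loc[a, samples].to_numpy(dtype=float)
        for b in matrix_b.index:
            yb = matrix_b.loc[b, samples].to_numpy(dtype=float)
            out.append(_result(a, b, group, xa, yb, alpha))
    return out


def peptide_heatmap_table(
    microbial: pd.DataFrame,
    markers: pd.DataFrame,
    design: pd.DataFrame,
    groups: list[str],
    fraction: str | None = None,
    min_abs_r: float = HEATMAP_MIN_R,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-level correlation table across groups + sign-reversal report.

    Returns ``(table, reversals)``. The table holds every (microbial
    peptide, marker peptide, group) correlation with its significance tier,
    filtered to pairs reaching |r| > ``min_abs_r`` in at least one group
    (self-pairs excluded). The reversal report lists pairs with r >= +0.5
    in one group and r <= -0.5 in another, both significant — the
    reversed-correlation pattern between controls and early disease.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for the heatmap screen")
    missing = set(groups) - set(design["group"])
    if missing:
        raise ValueError(f"groups absent from design: {sorted(missing)}")
    all_results: list[CorrelationResult] = []
    for group in groups:
        all_results.extend(
            correlate_pairs(microbial, markers, design, group, fraction, alpha)
        )
    df = results_to_frame(all_results)
    df = df[df["feature_a"] != df["feature_b"]]
    df["p_tier"] = df["p"].map(
        lambda p: "ns" if not np.isfinite(p) or p > 0.05
        else ("p<=0.001" if p <= 0.001 else "p<=0.01" if p <= 0.01 else "p<=0.05")
    )
    key = ["feature_a", "feature_b"]
    keep = (
        df.assign(hit=df["r"].abs() > min_abs_r)
        .groupby(key)["hit"]
        .any()
    )
    mask = keep.reindex(pd.MultiIndex.from_frame(df[key])).to_numpy()
    table = df[mask]

    reversal_rows = []
    for (a, b), sub in table.groupby(key):
        sig = sub[sub["significant"] == True]  # noqa: E712
        pos = sig[sig["r"] >= min_abs_r]
        neg = sig[sig["r"] <= -min_abs_r]
        if len(pos) and len(neg):
            reversal_rows.append(
                {
                    "feature_a": a,
                    "feature_b": b,
                    "positive_groups": ";".join(sorted(pos["group"])),
                    "negative_groups": ";".join(sorted(neg["group"])),
                    "r_positive": float(pos["r"].max()),
                    "r_negative": float(neg["r"].min()),
                }
            )
    reversals = pd.DataFrame(
        reversal_rows,
        columns=["feature_a", "feature_b", "positive_groups",
                 "negative_groups", "r_positive", "r_negative"],
    )
    return table.reset_index(drop=True), reversals


def detection_partition(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame
) -> dict[str, set[str]]:
    """Partition features by compartment detection (>0 in >= 1 sample)."""
    det_a = set(matrix_a.index[(matrix_a.fillna(0) > 0).any(axis=1)])
    det_b = set(matrix_b.index[(matrix_b.fillna(0) > 0).any(axis=1)])
    return {
        "a_only": det_a - det_b,
        "b_only": det_b - det_a,
        "common": det_a & det_b,
    }


def cross_compartment_correlation(
    bev_matrix: pd.DataFrame,
    wb_matrix: pd.DataFrame,
    design: pd.DataFrame,
    group: str | None = None,
    alpha: float = 0.05,
) -> tuple[list[CorrelationResult], dict[str, set[str]]]:
    """Per-protein correlation between paired EV and tissue levels.

    Samples are paired by (subject, replicate) — both fractions derive from
    the same tissue specimen. Only proteins detected in both compartments
    ("common") are correlated; the bEV-only/WB-only/common partition is
    returned alongside. Restricting to one group uses that group's pairs
    (n = subjects x replicates).
    """
    partition = detection_partition(bev_matrix, wb_matrix)
    design = design.copy()
    if group is not None:
        design = design[design["group"] == group]
    bev_design = design[design["sample_id"].isin(bev_matrix.columns)]
    wb_design = design[design["sample_id"].isin(wb_matrix.columns)]
    key = ["subject_id", "replicate"]
    paired = bev_design[key + ["sample_id"]].merge(
        wb_design[key + ["sample_id"]], on=key, suffixes=("_bev", "_wb")
    )
    results = []
    label = group if group is not None else "all"
    for acc in sorted(partition["common"]):
        x = bev_matrix.loc[acc, paired["sample_id_bev"]].to_numpy(dtype=float)
        y = wb_matrix.loc[acc, paired["sample_id_wb"]].to_numpy(dtype=float)
        results.append(_result(acc, acc, label, x, y, alpha))
    return results, partition


__all__ = [
    "STRONG_R",
    "VERY_STRONG_R",
    "HEATMAP_MIN_R",
    "strength_tier",
    "fisher_ci",
    "CorrelationResult",
    "results_to_frame",
    "correlate_pairs",
    "peptide_heatmap_table",
    "detection_partition",
    "cross_compartment_correlation",
]
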