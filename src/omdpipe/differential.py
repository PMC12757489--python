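"""Stage-wise modulation analysis.

Three pieces:

* fuzzy c-means clustering of standardized protein abundance profiles
  across disease stages (classic alternating-update algorithm, fuzzifier
  m = 2); proteins whose best membership falls below 0.5 are flagged
  unretained, and the number of clusters defaults to the value maximizing
  the fuzzy partition coefficient;
* gene-symbol isoform splitting — proteins sharing a symbol but landing in
  different trend clusters are relabeled with subscript indices (the
  DnaK_1..DnaK_4 situation), ordered deterministically by first-stage mean;
* the ANOVA family — one-way ANOVA with Bonferroni-corrected pairwise
  contrasts (primary), Fisher's LSD after a significant omnibus, one-way
  ANOVA on ranks, and two-way ANOVA (group x replicate batch) with
  Bonferroni pairwise contrasts — plus the deterministic dementia-category
  rules (AD / VaD / AD_progression / early_AD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import STAGE_INDEX

TEST_TAGS = (
    "anova_bonferroni",
    "anova_fisher_lsd",
    "kruskal_ranks",
    "two_way_anova_bonferroni",
)

SIGNIFICANCE_TIERS = ((0.001, "p<=0.001"), (0.01, "p<=0.01"), (0.05, "p<=0.05"))

#: symbol system used in the emulated study's figures, per test family
TIER_SYMBOLS = {
    "anova_bonferroni": {"p<=0.05": "*", "p<=0.01": "**", "p<=0.001": "**"},
    "two_way_anova_bonferroni": {"p<=0.05": "*", "p<=0.01": "**", "p<=0.001": "**"},
    "anova_fisher_lsd": {"p<=0.05": "+", "p<=0.01": "++", "p<=0.001": "++"},
    "kruskal_ranks": {"p<=0.05": "#", "p<=0.01": "#", "p<=0.001": "#"},
}


def significance_tier(p: float) -> str:
    for cut, label in SIGNIFICANCE_TIERS:
        if p <= cut:
            return label
    return "ns"


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    """Result of one fuzzy c-means run."""

    memberships: pd.DataFrame  # feature x cluster, rows sum to 1
    centroids: np.ndarray  # cluster x dim
    objective_path: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def n_clusters(self) -> int:
        return self.memberships.shape[1]

    @property
    def partition_coefficient(self) -> float:
        u = self.memberships.to_numpy()
        return float((u**2).sum() / u.shape[0])

    def assignments(self, threshold: float = 0.5) -> pd.DataFrame:
        """Hard assignment with membership value and retained flag."""
        u = self.memberships
        best = u.idxmax(axis=1)
        value = u.max(axis=1)
        return pd.DataFrame(
            {
                "cluster": best,
                "membership": value,
                "retained": value >= threshold,
            },
            index=u.index,
        )


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-score across stages; zero-variance rows become 0."""
    values = profiles.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (values - mean) / sd, index=profiles.index, columns=profiles.columns
    )


def fuzzy_cluster(
    profiles: pd.DataFrame,
    n_clusters: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
    standardize: bool = True,
) -> FuzzyClustering:
    """Classic fuzzy c-means on (standardized) stage profiles.

    Alternating membership/centroid updates until the maximum centroid
    shift drops below ``tol`` or ``max_iter`` is reached. The objective is
    asserted non-increasing along the path.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters >= profiles.shape[0]:
        raise ValueError("n_clusters must be smaller than the number of features")
    X = (
        standardize_profiles(profiles) if standardize else profiles
    ).to_numpy(dtype=float)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    centroids = np.zeros((n_clusters, d))
    objective_path: list[float] = []
    eps = 1e-12
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        new_centroids = (um.T @ X) / um.sum(axis=0)[:, None]
        dist2 = ((X[:, None, :] - new_centroids[None, :, :]) ** 2).sum(axis=2)
        dist2 = np.maximum(dist2, eps)
        # u_ik ∝ d_ik^(-2/(m-1)) = (d²)^(-1/(m-1))
        inv = dist2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        objective = float(((u**m) * dist2).sum())
        if objective_path and objective > objective_path[-1] + 1e-8:
            raise AssertionError("fuzzy c-means objective increased")
        objective_path.append(objective)
        shift = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if shift < tol:
            break
    memberships = pd.DataFrame(
        u,
        index=profiles.index,
        columns=[f"cluster{i + 1}" for i in range(n_clusters)],
    )
    return FuzzyClustering(memberships, centroids, objective_path, n_iter)


def select_n_clusters(
    profiles: pd.DataFrame,
    k_range: range = range(2, 9),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Pick k maximizing the fuzzy partition coefficient over ``k_range``."""
    scores: dict[int, float] = {}
    for k in k_range:
        if k >= profiles.shape[0]:
            break
        scores[k] = fuzzy_cluster(profiles, k, seed=seed).partition_coefficient
    if not scores:
        raise ValueError("no admissible k in range")
    best = max(scores, key=lambda k: (scores[k], -k))
    return best, scores


# ---------------------------------------------------------------------------
# isoform splitting
# ---------------------------------------------------------------------------

def split_isoforms(
    symbols: dict[str, str],
    assignments: pd.DataFrame,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Partition each gene symbol's proteins by trend cluster.

    ``symbols`` maps protein accession -> gene symbol. Within a symbol,
    proteins in different clusters become distinct isoforms labeled
    ``Symbol_1``, ``Symbol_2``, ... with subscripts assigned in descending
    order of the cluster's mean first-stage abundance (deterministic under
    cluster relabeling). A symbol whose members all share one cluster keeps
    its plain label.
    """
    first_col = profiles.columns[0]
    rows = []
    by_symbol: dict[str, list[str]] = {}
    for acc, sym in symbols.items():
        if acc in assignments.index:
            by_symbol.setdefault(sym, []).append(acc)
    for sym in sorted(by_symbol):
        members = sorted(by_symbol[sym])
        clusters = {acc: assignments.loc[acc, "cluster"] for acc in members}
        distinct = sorted(set(clusters.values()))
        if len(distinct) == 1:
            for acc in members:
                rows.append(
                    {"protein": acc, "symbol": sym, "cluster": clusters[acc],
                     "isoform": sym}
                )
            continue
        # order clusters by first-stage mean of their members, descending;
        # tie-break on cluster id for determinism
        def _key(cl: str) -> tuple[float, str]:
            accs = [a for a in members if clusters[a] == cl]
            return (-float(profiles.loc[accs, first_col].mean()), cl)

        ordered = sorted(distinct, key=_key)
        label_of = {cl: f"{sym}_{i + 1}" for i, cl in enumerate(ordered)}
        for acc in members:
            rows.append(
                {"protein": acc, "symbol": sym, "cluster": clusters[acc],
                 "isoform": label_of[clusters[acc]]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------

def _grouped_values(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    subject_level: bool,
) -> tuple[list[str], dict[str, pd.DataFrame]]:
    """Column groups of the matrix keyed by study group.

    ``subject_level`` averages technical replicates within subject first
    (the default unit of analysis); otherwise every run is an observation.
    """
    from .quantification import average_replicates

    design = design[design["sample_id"].isin(matrix.columns)]
    if subject_level:
        values = average_replicates(matrix, design)
        unit_group = (
            design.drop_duplicates("subject_id")
            .set_index("subject_id")["group"]
        )
    else:
        values = matrix
        unit_group = design.set_index("sample_id")["group"]
    groups = list(dict.fromkeys(design["group"]))
    split = {g: values[[c for c in values.columns if unit_group[c] == g]]
             for g in groups}
    return groups, split


def _pairwise_pooled_t(
    samples: list[np.ndarray], groups: list[str]
) -> tuple[pd.DataFrame, float, int]:
    """Pairwise contrasts via pooled-MSE t (classic post-hoc machinery)."""
    k = len(samples)
    ns = [len(s) for s in samples]
    N = sum(ns)
    means = [s.mean() for s in samples]
    sse = sum(((s - mu) ** 2).sum() for s, mu in zip(samples, means))
    df_err = N - k
    mse = sse / df_err if df_err > 0 else np.nan
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if df_err <= 0 or not np.isfinite(mse):
                p = np.nan
                tstat = np.nan
            elif mse <= 0:
                same = np.isclose(means[i], means[j])
                p = 1.0 if same else 0.0
                tstat = 0.0 if same else np.inf
            else:
                se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
                tstat = (means[i] - means[j]) / se
                p = 2.0 * stats.t.sf(abs(tstat), df_err)
            rows.append(
                {"group_a": groups[i], "group_b": groups[j],
                 "statistic": float(tstat), "raw_p": float(p)}
            )
    return pd.DataFrame(rows), mse, df_err


def run_tests(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    test: str = "anova_bonferroni",
    alpha: float = 0.05,
    subject_level: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature omnibus test plus pairwise contrasts.

    Returns ``(results, contrasts)``:

    * ``results`` — one row per feature: omnibus statistic and p, the
      minimum adjusted pairwise p (``adj_p``), a ``significant`` flag
      (omnibus p <= alpha and at least one adjusted contrast <= alpha), the
      significance tier with its figure symbol, and a ``degenerate`` flag
      for all-equal features (p reported as 1).
    * ``contrasts`` — long form per feature and group pair with raw and
      adjusted p (Bonferroni multiplies by the number of contrasts within
      the feature's family; Fisher's LSD reports unadjusted p and is only
      evaluated after a significant omnibus; the rank test reports the
      omnibus only).
    """
    if test not in TEST_TAGS:
        raise ValueError(f"unknown test tag {test!r}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    two_way = test == "two_way_anova_bonferroni"
    groups, split = _grouped_values(
        matrix, design, subject_level=subject_level and not two_way
    )
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    design_idx = design.set_index("sample_id")

    result_rows = []
    contrast_rows = []
    for feature in matrix.index:
        samples = [split[g].loc[feature].to_numpy(dtype=float) for g in groups]
        flat = np.concatenate(samples)
        degenerate = bool(np.allclose(flat, flat[0]))
        if degenerate:
            result_rows.append(
                {"feature": feature, "test": test, "statistic": np.nan,
                 "raw_p": 1.0, "adj_p": 1.0, "significant": False,
                 "tier": "ns", "symbol": "", "degenerate": True}
            )
            continue

        if test == "kruskal_ranks":
            stat, omni_p = stats.kruskal(*samples)
            adj_p = omni_p
            significant = omni_p <= alpha
        elif two_way:
            stat, omni_p = _two_way_group_p(matrix, feature, design_idx)
            pw, mse, df_err = _pairwise_pooled_t(samples, groups)
            pw["adj_p"] = (pw["raw_p"] * len(pw)).clip(upper=1.0)
            adj_p = float(pw["adj_p"].min())
            significant = omni_p <= alpha and adj_p <= alpha
            pw.insert(0, "feature", feature)
            contrast_rows.append(pw)
        else:
            stat, omni_p = stats.f_oneway(*samples)
            pw, mse, df_err = _pairwise_pooled_t(samples, groups)
            if test == "anova_bonferroni":
                pw["adj_p"] = (pw["raw_p"] * len(pw)).clip(upper=1.0)
                adj_p = float(pw["adj_p"].min())
                significant = omni_p <= alpha and adj_p <= alpha
            else:  # Fisher's LSD: unadjusted pairwise, gated on the omnibus
                pw["adj_p"] = pw["raw_p"]
                adj_p = float(pw["raw_p"].min())
                significant = omni_p <= alpha and adj_p <= alpha
            pw.insert(0, "feature", feature)
            contrast_rows.append(pw)

        tier = significance_tier(adj_p if significant else 1.0)
        result_rows.append(
            {"feature": feature, "test": test, "statistic": float(stat),
             "raw_p": float(omni_p), "adj_p": float(adj_p),
             "significant": bool(significant), "tier": tier,
             "symbol": TIER_SYMBOLS[test].get(tier, ""), "degenerate": False}
        )
    results = pd.DataFrame(result_rows)
    contrasts = (
        pd.concat(contrast_rows, ignore_index=True)
        if contrast_rows
        else pd.DataFrame(
            columns=["feature", "group_a", "group_b", "statistic", "raw_p", "adj_p"]
        )
    )
    return results, contrasts


def _two_way_group_p(
    matrix: pd.DataFrame, feature, design_idx: pd.DataFrame
) -> tuple[float, float]:
    """Group effect from a two-way ANOVA with replicate batch as the second
    factor (the only plausible second factor in this design)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    cols = [c for c in matrix.columns if c in design_idx.index]
    df = pd.DataFrame(
        {
            "value": matrix.loc[feature, cols].to_numpy(dtype=float),
            "group": design_idx.loc[cols, "group"].to_numpy(),
            "batch": design_idx.loc[cols, "replicate"].astype(str).to_numpy(),
        }
    )
    model = ols("value ~ C(group) + C(batch)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(group)", "F"]), float(
        table.loc["C(group)", "PR(>F)"]
    )


# ---------------------------------------------------------------------------
# dementia-category rules
# ---------------------------------------------------------------------------

def classify_dementia_category(
    group_means: pd.DataFrame,
    contrasts: pd.DataFrame,
    presence: pd.DataFrame,
    alpha: float = 0.05,
    monotone_rho: float = 0.8,
) -> pd.Series:
    """Deterministic category per protein: VaD / AD_progression / early_AD /
    AD / none.

    * VaD — present exclusively in VaD, absent only in VaD, or significant
      only against VaD;
    * AD_progression — stage means monotone along control..AD6 (|Spearman
      rho| >= ``monotone_rho``) with >= 1 significant stage contrast;
    * early_AD — significant AD3-vs-control contrast or presence exclusive
      to early AD;
    * AD — any other significant contrast among AD-axis groups;
    * none — nothing significant.
    """
    stage_groups = [g for g in group_means.columns if g in STAGE_INDEX]
    stage_groups.sort(key=lambda g: STAGE_INDEX[g])
    has_vad = "VaD" in group_means.columns

    sig = contrasts[contrasts["adj_p"] <= alpha]
    sig_pairs: dict[str, set[frozenset]] = {}
    for row in sig.itertuples():
        sig_pairs.setdefault(row.feature, set()).add(
            frozenset((row.group_a, row.group_b))
        )

    out = {}
    for acc in group_means.index:
        pairs = sig_pairs.get(acc, set())
        ad_axis_sig = {p for p in pairs if "VaD" not in p}
        vad_sig = pairs - ad_axis_sig
        pres = presence.loc[acc] if acc in presence.index else None

        def _exclusive(target: str, value: bool) -> bool:
            if pres is None or target not in pres.index:
                return False
            others = [g for g in pres.index if g != target]
            return bool(pres[target]) == value and all(
                bool(pres[g]) != value for g in others
            )

        category = "none"
        if has_vad and (_exclusive("VaD", True) or _exclusive("VaD", False)):
            category = "VaD"
        else:
            means = group_means.loc[acc, stage_groups].to_numpy(dtype=float)
            stages = [STAGE_INDEX[g] for g in stage_groups]
            rho = 0.0
            if np.ptp(means) > 0:
                rho = stats.spearmanr(stages, means).statistic
            if abs(rho) >= monotone_rho and ad_axis_sig:
                category = "AD_progression"
            elif frozenset(("control", "AD3")) in pairs or _exclusive("AD3", True):
                category = "early_AD"
            elif vad_sig and not ad_axis_sig:
                category = "VaD"
            elif ad_axis_sig:
                category = "AD"
        out[acc] = category
    return pd.Series(out, name="category")


__all__ = [
    "TEST_TAGS",
    "TIER_SYMBOLS",
    "significance_tier",
    "FuzzyClustering",
    "standardize_profiles",
    "fuzzy_cluster",
    "select_n_clusters",
    "split_isoforms",
    "run_tests",
    "classify_dementia_category",
]
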