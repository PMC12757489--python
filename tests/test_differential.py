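"""Fuzzy c-means, isoform splitting, ANOVA family and category rules."""

import numpy as np
import pandas as pd
import pytest

from omdpipe.differential import (
    classify_dementia_category,
    fuzzy_cluster,
    run_tests,
    select_n_clusters,
    significance_tier,
    split_isoforms,
)
from omdpipe.quantification import group_mean_matrix
from omdpipe.synthetic_data import (
    GROUPS_BRAAK,
    make_design,
    simulate_protein_counts,
)

GROUP_COLS = list(GROUPS_BRAAK)


def _profiles(n_up=20, n_down=20, seed=0):
    rng = np.random.default_rng(seed)
    up = np.cumsum(rng.uniform(0.5, 1.5, size=(n_up, 6)), axis=1)
    down = up[:, ::-1][:n_down] + rng.normal(0, 0.05, size=(n_down, 6))
    data = np.vstack([up, down])
    idx = [f"U{i}" for i in range(n_up)] + [f"D{i}" for i in range(n_down)]
    return pd.DataFrame(data, index=idx, columns=GROUP_COLS)


class TestFuzzyCluster:
    def test_memberships_row_sum_to_one(self):
        fc = fuzzy_cluster(_profiles(), 3, seed=1)
        sums = fc.memberships.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_objective_non_increasing(self):
        fc = fuzzy_cluster(_profiles(), 2, seed=2)
        path = np.array(fc.objective_path)
        assert (np.diff(path) <= 1e-8).all()

    def test_recovers_planted_families(self):
        """Monotone-up vs monotone-down profiles are separated with
        membership >= 0.5 for >= 95% of features, across seeds."""
        agree = total = 0
        for seed in range(20):
            prof = _profiles(seed=seed)
            fc = fuzzy_cluster(prof, 2, seed=seed)
            a = fc.assignments()
            fam = pd.Series([i[0] for i in a.index], index=a.index)
            mapping = (
                a.assign(f=fam).groupby("cluster")["f"].agg(lambda s: s.mode()[0])
            )
            ok = (fam == a["cluster"].map(mapping)) & a["retained"]
            agree += int(ok.sum())
            total += len(ok)
        assert agree / total >= 0.95

    def test_duplicated_profiles_give_half_memberships(self):
        prof = pd.DataFrame(np.ones((8, 6)), columns=GROUP_COLS)
        fc = fuzzy_cluster(prof, 2, seed=0)
        assert np.allclose(fc.memberships.to_numpy(), 0.5, atol=1e-6)

    def test_too_many_clusters_raise(self):
        with pytest.raises(ValueError):
            fuzzy_cluster(_profiles(n_up=2, n_down=1), 3)

    def test_select_k_returns_admissible_k(self):
        k, scores = select_n_clusters(_profiles(), range(2, 5), seed=0)
        assert k in scores and 2 <= k <= 4
        assert scores[k] == max(scores.values())


class TestSplitIsoforms:
    def _assignments(self):
        return pd.DataFrame(
            {
                "cluster": ["c1", "c2", "c3", "c4", "c1"],
                "membership": [0.9] * 5,
                "retained": [True] * 5,
            },
            index=["dk1", "dk2", "dk3", "dk4", "solo"],
        )

    def _profiles(self):
        return pd.DataFrame(
            {"control": [40.0, 30.0, 20.0, 10.0, 5.0],
             "AD3": [1.0] * 5},
            index=["dk1", "dk2", "dk3", "dk4", "solo"],
        )

    def test_four_clusters_make_four_isoforms(self):
        symbols = {f"dk{i}": "DnaK" for i in range(1, 5)}
        out = split_isoforms(symbols, self._assignments(), self._profiles())
        labels = set(out["isoform"])
        assert labels == {"DnaK_1", "DnaK_2", "DnaK_3", "DnaK_4"}
        # subscripts follow first-stage mean descending
        assert out.set_index("protein").loc["dk1", "isoform"] == "DnaK_1"
        assert out.set_index("protein").loc["dk4", "isoform"] == "DnaK_4"

    def test_single_member_keeps_plain_label(self):
        out = split_isoforms({"solo": "AHCY"}, self._assignments(),
                             self._profiles())
        assert out["isoform"].tolist() == ["AHCY"]

    def test_relabeling_clusters_keeps_subscripts(self):
        symbols = {f"dk{i}": "DnaK" for i in range(1, 5)}
        a = self._assignments()
        permuted = a.copy()
        permuted["cluster"] = a["cluster"].map(
            {"c1": "z9", "c2": "z8", "c3": "z7", "c4": "z6"}
        )
        out1 = split_isoforms(symbols, a, self._profiles())
        out2 = split_isoforms(symbols, permuted, self._profiles())
        assert (
            out1.set_index("protein")["isoform"].to_dict()
            == out2.set_index("protein")["isoform"].to_dict()
        )


class TestRunTests:
    def test_degenerate_all_equal_reports_p_one(self):
        design = make_design(groups=("control", "AD3", "AD4"),
                             fractions=("bEV",))
        mat = pd.DataFrame(
            np.ones((2, len(design))), index=["P1", "P2"],
            columns=design["sample_id"],
        )
        results, _ = run_tests(mat, design)
        assert (results["raw_p"] == 1.0).all()
        assert results["degenerate"].all()
        assert not results["significant"].any()

    def test_bonferroni_multiplication_rule(self):
        design = make_design(fractions=("bEV",))  # 6 groups -> 15 contrasts
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(
            rng.normal(10, 1, size=(3, len(design))),
            index=["P1", "P2", "P3"], columns=design["sample_id"],
        )
        _, contrasts = run_tests(mat, design, test="anova_bonferroni")
        per_feature = contrasts.groupby("feature").size()
        assert (per_feature == 15).all()
        expected = (contrasts["raw_p"] * 15).clip(upper=1.0)
        assert np.allclose(contrasts["adj_p"], expected)

    def test_invariant_to_feature_and_sample_order(self):
        design = make_design(groups=("control", "AD3"), fractions=("bEV",))
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.poisson(20, size=(4, len(design))).astype(float),
            index=list("ABCD"), columns=design["sample_id"],
        )
        r1, _ = run_tests(mat, design)
        r2, _ = run_tests(
            mat.iloc[::-1][list(reversed(mat.columns))], design
        )
        m1 = r1.set_index("feature")["raw_p"]
        m2 = r2.set_index("feature")["raw_p"]
        assert np.allclose(m1.sort_index(), m2.sort_index())

    @pytest.mark.parametrize(
        "tag", ["anova_fisher_lsd", "kruskal_ranks", "two_way_anova_bonferroni"]
    )
    def test_other_tags_run_and_flag_strong_effects(self, tag):
        design = make_design(groups=("control", "AD3", "AD4"),
                             fractions=("bEV",))
        trends = {"UP": "up_with_stage", "FLAT": "flat"}
        mat = simulate_protein_counts(trends, design, effect_size=4,
                                      dropout_rate=0.0, seed=5).fillna(0)
        results, _ = run_tests(mat, design, test=tag)
        sig = results.set_index("feature")["significant"]
        assert bool(sig["UP"])

    def test_null_type_one_error_controlled(self):
        """Exchangeable groups: feature-wise FWER stays near alpha."""
        design = make_design(fractions=("bEV",))
        trends = {f"P{i}": "flat" for i in range(400)}
        mat = simulate_protein_counts(trends, design, effect_size=2,
                                      dropout_rate=0.0, seed=17).fillna(0)
        results, _ = run_tests(mat, design)
        assert results["significant"].mean() <= 0.06

    def test_tier_mapping(self):
        assert significance_tier(0.04) == "p<=0.05"
        assert significance_tier(0.009) == "p<=0.01"
        assert significance_tier(0.0005) == "p<=0.001"
        assert significance_tier(0.2) == "ns"


class TestClassification:
    def _run(self, trends, seed=23, effect=6):
        design = make_design(fractions=("bEV",))
        mat = simulate_protein_counts(trends, design, effect_size=effect,
                                      dropout_rate=0.0, seed=seed).fillna(0)
        _, contrasts = run_tests(mat, design)
        profiles = group_mean_matrix(mat, design, GROUP_COLS)
        presence = (profiles > 0)
        return classify_dementia_category(profiles, contrasts, presence)

    def test_planted_examples(self):
        trends = {
            "V": "vad_only",
            "U": "up_with_stage",
            "F": "flat",
            "E": "early_peak",
            "A": "absent_in_vad",
        }
        cats = self._run(trends)
        assert cats["V"] == "VaD"
        assert cats["U"] == "AD_progression"
        assert cats["F"] == "none"
        assert cats["E"] == "early_AD"
        assert cats["A"] == "VaD"
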