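"""Pearson screens: tiers, CIs, reversal detection, null behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omdpipe.correlation import (
    correlate_pairs,
    cross_compartment_correlation,
    detection_partition,
    fisher_ci,
    peptide_heatmap_table,
    results_to_frame,
    strength_tier,
)
from omdpipe.synthetic_data import make_design


def _design(groups=("control", "AD3"), n_subjects=5, fractions=("bEV",)):
    return make_design(groups=groups, n_subjects=n_subjects,
                       fractions=fractions)


def _matrix(rows, design):
    return pd.DataFrame(rows, columns=design["sample_id"])


class TestTiers:
    def test_boundary_values_exact(self):
        assert strength_tier(0.70) == "strong"
        assert strength_tier(0.699999) == "none"
        assert strength_tier(0.85) == "very_strong"
        assert strength_tier(0.849999) == "strong"
        assert strength_tier(-0.9) == "very_strong"


class TestCorrelatePairs:
    def test_exact_linearity_gives_r_one(self):
        design = _design(groups=("control",), n_subjects=4, fractions=("bEV",))
        design = design[design["replicate"] == 1]
        a = _matrix([[1.0, 2.0, 3.0, 4.0]], design).rename(index={0: "x"})
        b = _matrix([[2.0, 4.0, 6.0, 8.0]], design).rename(index={0: "y"})
        (res,) = correlate_pairs(a, b, design, "control")
        assert res.r == pytest.approx(1.0)
        assert res.tier == "very_strong"
        assert res.ci_low <= res.r <= res.ci_high

    def test_negation_flips_sign(self):
        design = _design(groups=("control",), n_subjects=4, fractions=("bEV",))
        design = design[design["replicate"] == 1]
        a = _matrix([[1.0, 2.0, 5.0, 4.0]], design).rename(index={0: "x"})
        b = -a.rename(index={"x": "y"})
        (res,) = correlate_pairs(a, b, design, "control")
        assert res.r == pytest.approx(-1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=5, unique=True),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_invariant_under_positive_affine_transform(self, xs, scale, shift):
        design = _design(groups=("control",), n_subjects=5, fractions=("bEV",))
        design = design[design["replicate"] == 1]
        rng = np.random.default_rng(0)
        ys = rng.normal(size=5)
        a = _matrix([xs], design).rename(index={0: "x"})
        b = _matrix([ys], design).rename(index={0: "y"})
        (base,) = correlate_pairs(a, b, design, "control")
        (scaled,) = correlate_pairs(a * scale + shift, b, design, "control")
        if base.flag or scaled.flag:
            return
        assert scaled.r == pytest.approx(base.r, abs=1e-8)

    def test_too_few_samples_flagged(self):
        design = _design(groups=("control",), n_subjects=2, fractions=("bEV",))
        design = design[design["replicate"] == 1]
        a = _matrix([[1.0, 2.0]], design).rename(index={0: "x"})
        (res,) = correlate_pairs(a, a.rename(index={"x": "y"}), design,
                                 "control")
        assert res.flag == "too_few"

    def test_zero_variance_flagged(self):
        design = _design(groups=("control",), n_subjects=4, fractions=("bEV",))
        design = design[design["replicate"] == 1]
        a = _matrix([[3.0, 3.0, 3.0, 3.0]], design).rename(index={0: "x"})
        b = _matrix([[1.0, 2.0, 3.0, 4.0]], design).rename(index={0: "y"})
        (res,) = correlate_pairs(a, b, design, "control")
        assert res.flag == "zero_variance"

    def test_unknown_group_raises(self):
        design = _design()
        a = _matrix([np.ones(len(design))], design)
        with pytest.raises(ValueError):
            correlate_pairs(a, a, design, "nonexistent")

    def test_null_pairs_rarely_significant(self):
        """Independent features: p <= 0.05 at roughly the nominal rate."""
        design = _design(groups=("control",), n_subjects=10, fractions=("bEV",))
        rng = np.random.default_rng(42)
        a = pd.DataFrame(rng.normal(size=(25, len(design))),
                         columns=design["sample_id"],
                         index=[f"a{i}" for i in range(25)])
        b = pd.DataFrame(rng.normal(size=(40, len(design))),
                         columns=design["sample_id"],
                         index=[f"b{i}" for i in range(40)])
        results = correlate_pairs(a, b, design, "control")
        frac = np.mean([r.significant for r in results])
        assert frac <= 0.06


class TestHeatmapTable:
    def _planted(self):
        design = _design(groups=("control", "AD3"), n_subjects=4)
        rng = np.random.default_rng(1)
        n = len(design)
        group = design.set_index("sample_id")["group"]
        z = rng.normal(size=n)
        x = z + rng.normal(0, 0.3, n)
        y = np.where(group.to_numpy() == "control", 1, -1) * z + rng.normal(0, 0.3, n)
        mats = pd.DataFrame(
            [x, y, rng.normal(size=n)],
            index=["mic1", "marker1", "mic2"],
            columns=design["sample_id"],
        )
        return design, mats

    def test_signflip_pair_lands_in_reversal_report(self):
        design, mats = self._planted()
        table, reversals = peptide_heatmap_table(
            mats.loc[["mic1", "mic2"]], mats.loc[["marker1"]],
            design, ["control", "AD3"],
        )
        pairs = set(zip(reversals["feature_a"], reversals["feature_b"]))
        assert ("mic1", "marker1") in pairs

    def test_weak_pairs_filtered_out(self):
        design = _design(groups=("control", "AD3"), n_subjects=6)
        rng = np.random.default_rng(5)
        a = pd.DataFrame(rng.normal(size=(1, len(design))), index=["x"],
                         columns=design["sample_id"])
        # y constructed nearly orthogonal to x within each group
        y = pd.DataFrame(rng.normal(size=(1, len(design))) * 1e-3
                         + np.arange(len(design)) * 0,
                         index=["y"], columns=design["sample_id"])
        table, _ = peptide_heatmap_table(a, y, design, ["control", "AD3"])
        if not table.empty:
            by_pair = table.groupby(["feature_a", "feature_b"])["r"]
            assert (by_pair.apply(lambda s: (s.abs() > 0.5).any())).all()

    def test_self_pairs_excluded(self):
        design, mats = self._planted()
        table, reversals = peptide_heatmap_table(
            mats, mats, design, ["control", "AD3"]
        )
        assert not ((table["feature_a"] == table["feature_b"]).any())
        assert not (
            (reversals["feature_a"] == reversals["feature_b"]).any()
            if not reversals.empty else False
        )

    def test_missing_group_raises(self):
        design, mats = self._planted()
        with pytest.raises(ValueError):
            peptide_heatmap_table(mats, mats, design, ["control", "ghost"])


class TestCrossCompartment:
    def test_identical_values_give_r_one(self):
        design = _design(groups=("control",), n_subjects=4,
                         fractions=("bEV", "WB"))
        bev_cols = design[design["fraction"] == "bEV"]["sample_id"]
        wb_cols = design[design["fraction"] == "WB"]["sample_id"]
        rng = np.random.default_rng(2)
        vals = rng.poisson(20, size=len(bev_cols)).astype(float)
        bev = pd.DataFrame([vals], index=["P1"], columns=bev_cols)
        wb = pd.DataFrame([vals], index=["P1"], columns=wb_cols)
        results, partition = cross_compartment_correlation(bev, wb, design)
        assert partition["common"] == {"P1"}
        assert results[0].r == pytest.approx(1.0)

    def test_partition_equals_set_operations(self, bundle, attrib,
                                             protein_matrix):
        design = bundle.design
        bev = protein_matrix[
            design[design["fraction"] == "bEV"]["sample_id"]
        ]
        wb = protein_matrix[design[design["fraction"] == "WB"]["sample_id"]]
        partition = detection_partition(bev, wb)
        det_bev = {a for a in bev.index if (bev.loc[a] > 0).any()}
        det_wb = {a for a in wb.index if (wb.loc[a] > 0).any()}
        assert partition["a_only"] == det_bev - det_wb
        assert partition["b_only"] == det_wb - det_bev
        assert partition["common"] == det_bev & det_wb

    def test_planted_anticorrelated_pairs_detected(self, bundle, attrib,
                                                   protein_matrix):
        design = bundle.design
        bev = protein_matrix[
            design[design["fraction"] == "bEV"]["sample_id"]
        ]
        wb = protein_matrix[design[design["fraction"] == "WB"]["sample_id"]]
        results, _ = cross_compartment_correlation(bev, wb, design)
        df = results_to_frame(results).set_index("feature_a")
        planted = [a for a in bundle.truth.compartment_pairs if a in df.index]
        assert planted, "no planted compartment pair was quantifiable"
        sub = df.loc[planted]
        assert (sub["r"] <= -0.7).all()
        assert sub["significant"].all()

    def test_no_common_proteins_returns_empty(self):
        design = _design(groups=("control",), n_subjects=3,
                         fractions=("bEV", "WB"))
        bev_cols = design[design["fraction"] == "bEV"]["sample_id"]
        wb_cols = design[design["fraction"] == "WB"]["sample_id"]
        bev = pd.DataFrame([[1.0] * len(bev_cols)], index=["A"],
                           columns=bev_cols)
        wb = pd.DataFrame([[1.0] * len(wb_cols)], index=["B"],
                          columns=wb_cols)
        results, partition = cross_compartment_correlation(bev, wb, design)
        assert results == [] and partition["common"] == set()


def test_fisher_ci_contains_r():
    for r in (-0.9, -0.3, 0.0, 0.5, 0.95):
        lo, hi = fisher_ci(r, 30)
        assert lo <= r <= hi
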