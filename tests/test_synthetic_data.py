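"""Generator contracts: determinism, planted structure, count model."""

import filecmp

import numpy as np
import pandas as pd
import pytest

from omdpipe.digestion import build_peptide_index
from omdpipe.synthetic_data import (
    CorrelationPair,
    SyntheticTruth,
    label_provenance,
    make_bundle,
    make_databases,
    make_design,
    make_quant_tables,
    read_bundle,
    simulate_protein_counts,
    trend_mean,
    write_bundle,
)


class TestMakeDatabases:
    def test_deterministic_fasta_bytes(self, tmp_path):
        for run in ("a", "b"):
            mic, host = make_databases(n_taxa=4, proteins_per_taxon=2,
                                       host_size=5, seed=42)
            from omdpipe.proteome_db import write_fasta

            write_fasta(mic, tmp_path / f"m_{run}.fasta")
            write_fasta(host, tmp_path / f"h_{run}.fasta")
        assert filecmp.cmp(tmp_path / "m_a.fasta", tmp_path / "m_b.fasta",
                           shallow=False)
        assert filecmp.cmp(tmp_path / "h_a.fasta", tmp_path / "h_b.fasta",
                           shallow=False)

    def test_database_sizes(self):
        mic, host = make_databases(n_taxa=3, proteins_per_taxon=2,
                                   host_size=4, seed=0)
        assert len(mic) == 6
        assert len(host) == 4
        assert len(mic.taxa) == 3

    def test_invalid_sizes_raise(self):
        with pytest.raises(ValueError):
            make_databases(n_taxa=0)

    def test_planted_il_homologs_labeled_by_construction(self, bundle, index):
        labels = label_provenance(index, bundle.host)
        counts = pd.Series(labels).value_counts()
        assert counts.get("host_il_homologous", 0) >= 1
        assert counts.get("host_homologous", 0) >= 1
        assert counts.get("shared_multiprotein", 0) >= 1
        # an il-homologous peptide never occurs verbatim in the host
        from omdpipe.host_filter import canonicalize_il

        for pep, label in labels.items():
            if label == "host_il_homologous":
                assert not any(pep in rec.sequence for rec in bundle.host)
                assert any(
                    canonicalize_il(pep) in canonicalize_il(rec.sequence)
                    for rec in bundle.host
                )


class TestCountModel:
    def test_trend_mean_shapes(self):
        assert trend_mean("up_with_stage", "AD6", 10, 2) == 160
        assert trend_mean("up_with_stage", "control", 10, 2) == 10
        assert trend_mean("vad_only", "AD4", 10, 2) == 0
        assert trend_mean("vad_only", "VaD", 10, 2) == 20
        assert trend_mean("absent_in_vad", "VaD", 10, 2) == 0

    def test_up_trend_realized_in_group_means(self):
        """Monte-Carlo check: effect 2 over four stage steps gives a
        mean(AD6)/mean(control) ratio near 2^4 = 16."""
        design = make_design(fractions=("bEV",))
        trends = {f"P{i}": "up_with_stage" for i in range(250)}
        mat = simulate_protein_counts(trends, design, effect_size=2,
                                      dropout_rate=0.0, seed=3)
        group = design.set_index("sample_id")["group"]
        ad6 = mat[[c for c in mat if group[c] == "AD6"]].to_numpy().mean()
        ctl = mat[[c for c in mat if group[c] == "control"]].to_numpy().mean()
        assert 16 * 0.8 <= ad6 / ctl <= 16 * 1.2

    def test_zero_dropout_has_no_missing(self, bundle):
        design = make_design(fractions=("bEV",))
        quant = make_quant_tables(bundle.truth, design, dropout_rate=0.0,
                                  seed=1)
        assert quant["count"].notna().all()

    def test_dropout_rate_roughly_respected(self):
        design = make_design(fractions=("bEV",))
        trends = {f"P{i}": "flat" for i in range(300)}
        mat = simulate_protein_counts(trends, design, dropout_rate=0.2,
                                      seed=5)
        frac = mat.isna().to_numpy().mean()
        assert 0.1 < frac < 0.3

    def test_planted_pair_r_in_sampling_envelope(self):
        """Planted r = 0.9 at n = 30 lands inside the sampling band."""
        design = make_design(n_subjects=10, fractions=("bEV",))
        truth = SyntheticTruth(
            provenance={"AAA": "microbial_only", "BBB": "microbial_only"},
            protein_trend={"P1": "flat", "P2": "flat"},
            peptide_protein={"AAA": "P1", "BBB": "P2"},
            protein_fractions={"P1": ["bEV"], "P2": ["bEV"]},
            correlation_pairs=[CorrelationPair("AAA", "BBB", "control", 0.9)],
        )
        quant = make_quant_tables(truth, design, dropout_rate=0.0, seed=8)
        wide = quant.pivot(index="peptide", columns="sample_id",
                           values="count")
        group = design.set_index("sample_id")["group"]
        cols = [c for c in wide.columns if group[c] == "control"]
        r = np.corrcoef(wide.loc["AAA", cols].astype(float),
                        wide.loc["BBB", cols].astype(float))[0, 1]
        assert 0.75 <= r <= 0.97

    def test_bad_parameters_raise(self, bundle):
        design = make_design()
        with pytest.raises(ValueError):
            make_quant_tables(bundle.truth, design, effect_size=0)
        with pytest.raises(ValueError):
            make_quant_tables(bundle.truth, design, dropout_rate=1.0)

    def test_incompatible_design_groups_raise(self, bundle):
        design = make_design(groups=("control", "weird_group"))
        with pytest.raises(ValueError):
            make_quant_tables(bundle.truth, design)


class TestBundleIO:
    def test_truth_covers_every_quantified_peptide(self, bundle):
        assert set(bundle.quant["peptide"]) <= set(bundle.truth.provenance)

    def test_roundtrip_equals(self, tmp_path, bundle):
        write_bundle(bundle, tmp_path / "b")
        back = read_bundle(tmp_path / "b")
        a = bundle.quant.fillna(-1).reset_index(drop=True)
        b = back.quant.fillna(-1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            a, b[a.columns], check_dtype=False
        )
        assert back.truth.provenance == bundle.truth.provenance
        assert back.truth.protein_trend == bundle.truth.protein_trend

    def test_same_seed_identical_truth_json(self, tmp_path):
        for run in ("x", "y"):
            b = make_bundle(seed=21, n_taxa=4, proteins_per_taxon=2,
                            host_size=6)
            write_bundle(b, tmp_path / run)
        assert filecmp.cmp(tmp_path / "x" / "truth.json",
                           tmp_path / "y" / "truth.json", shallow=False)
        assert filecmp.cmp(tmp_path / "x" / "peptides.tsv",
                           tmp_path / "y" / "peptides.tsv", shallow=False)
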