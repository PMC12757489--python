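"""End-to-end orchestration: digest -> index -> host filter -> attribute ->
quantify -> stats -> correlations, with a declarative config and a
reproducibility manifest (input checksums, config, versions, seed, output
checksums). Given deterministic policies, re-running a saved config on the
same inputs yields byte-identical outputs and manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .attribution import attribute, common_sets, presence_by_condition
from .correlation import (
    cross_compartment_correlation,
    peptide_heatmap_table,
    results_to_frame,
)
from .differential import (
    classify_dementia_category,
    fuzzy_cluster,
    run_tests,
    select_n_clusters,
    split_isoforms,
)
from .digestion import build_peptide_index
from .host_filter import filter_host_homologs
from .proteome_db import read_fasta, read_taxon_annotations
from .quantification import (
    censored_impute_log2,
    group_mean_matrix,
    group_summarize,
    pivot_peptides,
    rollup_to_protein,
    zero_fill,
)

logger = logging.getLogger(__name__)

STAGES = (
    "digest",
    "index",
    "host_filter",
    "attribute",
    "quantify",
    "stats",
    "correlate",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    microbial_fasta: str = "microbial.fasta"
    host_fasta: str = "host.fasta"
    annotations_tsv: str = "annotations.tsv"
    peptides_tsv: str = "peptides.tsv"
    design_tsv: str = "design.tsv"
    outdir: str = "pipeline_out"

    max_missed: int = 2
    min_len: int = 7
    max_len: int = 22
    filter_mode: str = "substring"  # or "tryptic"
    impute_policy: str = "half_min"  # or "downshift"
    test: str = "anova_bonferroni"
    alpha: float = 0.05
    n_clusters: int = 0  # 0 = choose by partition coefficient
    membership_threshold: float = 0.5
    strong_r: float = 0.70
    very_strong_r: float = 0.85
    heatmap_min_r: float = 0.5
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def validate_config(config: PipelineConfig) -> list[str]:
    """All range checks, aggregated (never first-fail)."""
    errors = []
    if not 0 < config.alpha < 1:
        errors.append(f"alpha must be in (0, 1), got {config.alpha}")
    if not 0 < config.min_len <= config.max_len:
        errors.append(
            f"length window invalid: min_len={config.min_len} "
            f"max_len={config.max_len}"
        )
    if config.max_missed < 0:
        errors.append(f"max_missed must be >= 0, got {config.max_missed}")
    if config.filter_mode not in ("substring", "tryptic"):
        errors.append(f"unknown filter_mode {config.filter_mode!r}")
    if config.impute_policy not in ("half_min", "downshift"):
        errors.append(f"unknown impute_policy {config.impute_policy!r}")
    if not 0 < config.membership_threshold <= 1:
        errors.append(
            f"membership_threshold must be in (0, 1], got "
            f"{config.membership_threshold}"
        )
    for name in ("strong_r", "very_strong_r", "heatmap_min_r"):
        value = getattr(config, name)
        if not 0 < value <= 1:
            errors.append(f"{name} must be in (0, 1], got {value}")
    if config.n_clusters < 0:
        errors.append(f"n_clusters must be >= 0, got {config.n_clusters}")
    return errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write all outputs plus ``manifest.json``.

    Returns the manifest dict. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    errors = validate_config(config)
    if errors:
        raise PipelineError("validate", "; ".join(errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "microbial_fasta": Path(config.microbial_fasta),
        "host_fasta": Path(config.host_fasta),
        "annotations_tsv": Path(config.annotations_tsv),
        "peptides_tsv": Path(config.peptides_tsv),
        "design_tsv": Path(config.design_tsv),
    }
    for name, path in inputs.items():
        if not path.exists():
            raise PipelineError("validate", f"input {name} missing: {path}")

    stage = "digest"
    try:
        microbial = read_fasta(inputs["microbial_fasta"], kind="microbial")
        host = read_fasta(inputs["host_fasta"], kind="host")
        annotations = read_taxon_annotations(
            inputs["annotations_tsv"], known_taxa=microbial.taxa
        )
        quant = pd.read_csv(inputs["peptides_tsv"], sep="\t")
        quant["count"] = pd.to_numeric(quant["count"], errors="coerce")
        design = pd.read_csv(inputs["design_tsv"], sep="\t")

        stage = "index"
        index = build_peptide_index(
            microbial,
            max_missed=config.max_missed,
            min_len=config.min_len,
            max_len=config.max_len,
        )

        stage = "host_filter"
        observed = list(dict.fromkeys(quant["peptide"]))
        retained, report = filter_host_homologs(
            observed, host, mode=config.filter_mode
        )
        report.to_tsv(outdir / "filter_report.tsv")
        quant = quant[quant["peptide"].isin(set(retained))]

        stage = "attribute"
        attrib = attribute(retained, index, annotations)
        attrib.to_tsv(outdir / "attribution.tsv")
        (outdir / "orphans.txt").write_text(
            "\n".join(attrib.orphans) + ("\n" if attrib.orphans else "")
        )
        presence = presence_by_condition(attrib, quant, design, level="taxon")
        presence.to_csv(outdir / "presence_taxon.tsv", sep="\t")
        commons = common_sets(attrib, design, quant, annotations)
        with open(outdir / "common_sets.json", "w") as fh:
            json.dump(commons, fh, indent=1, sort_keys=True)

        stage = "quantify"
        pep_wide, n_filled = zero_fill(pivot_peptides(quant))
        protein_matrix = rollup_to_protein(pep_wide, attrib)
        protein_matrix.to_csv(outdir / "protein_matrix.tsv", sep="\t")
        summary = group_summarize(protein_matrix, design)
        summary.to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
        log2_matrix = censored_impute_log2(
            protein_matrix, policy=config.impute_policy, seed=config.seed
        )
        log2_matrix.to_csv(outdir / "log2_matrix.tsv", sep="\t")

        stage = "stats"
        groups = list(dict.fromkeys(design["group"]))
        profiles = group_mean_matrix(protein_matrix, design, groups)
        active = profiles[(profiles.sum(axis=1) > 0)]
        stats_out = {}
        if active.shape[0] >= 3:
            k = config.n_clusters or select_n_clusters(active, seed=config.seed)[0]
            clustering = fuzzy_cluster(active, k, seed=config.seed)
            assignments = clustering.assignments(config.membership_threshold)
            assignments.to_csv(outdir / "clusters.tsv", sep="\t")
            symbols = {
                rec.accession: rec.gene_symbol
                for rec in microbial
                if rec.accession in assignments.index
            }
            isoforms = split_isoforms(symbols, assignments, active)
            isoforms.to_csv(outdir / "isoforms.tsv", sep="\t", index=False)
            stats_out["n_clusters"] = k
            stats_out["partition_coefficient"] = clustering.partition_coefficient
        results, contrasts = run_tests(
            protein_matrix, design, test=config.test, alpha=config.alpha
        )
        results.to_csv(outdir / "stats_results.tsv", sep="\t", index=False)
        contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
        pres_protein = presence_by_condition(attrib, quant, design, level="protein")
        categories = classify_dementia_category(
            profiles, contrasts, pres_protein, alpha=config.alpha
        )
        categories.to_frame().to_csv(outdir / "categories.tsv", sep="\t")

        stage = "correlate"
        fractions = list(dict.fromkeys(design["fraction"]))
        if len(fractions) >= 2:
            bev_cols = design.loc[
                design["fraction"] == fractions[0], "sample_id"
            ]
            wb_cols = design.loc[
                design["fraction"] == fractions[1], "sample_id"
            ]
            bev = protein_matrix[[c for c in bev_cols if c in protein_matrix]]
            wb = protein_matrix[[c for c in wb_cols if c in protein_matrix]]
            cross, partition = cross_compartment_correlation(bev, wb, design)
            results_to_frame(cross).to_csv(
                outdir / "cross_compartment.tsv", sep="\t", index=False
            )
            with open(outdir / "compartment_partition.json", "w") as fh:
                json.dump(
                    {k: sorted(v) for k, v in partition.items()},
                    fh, indent=1, sort_keys=True,
                )
        # peptidome-wide screen among the most abundant retained peptides
        unique_peps = sorted(attrib.unique_to_protein())
        pep_bev = pep_wide.loc[
            [p for p in pep_wide.index if p in set(unique_peps)],
            [c for c in pep_wide.columns
             if design.set_index("sample_id").loc[c, "fraction"] == fractions[0]],
        ]
        top = pep_bev.mean(axis=1).nlargest(min(40, pep_bev.shape[0])).index
        heat_groups = groups[:2]
        table, reversals = peptide_heatmap_table(
            pep_bev.loc[top], pep_bev.loc[top], design, heat_groups,
            fraction=fractions[0], min_abs_r=config.heatmap_min_r,
            alpha=config.alpha,
        )
        table.to_csv(outdir / "heatmap_table.tsv", sep="\t", index=False)
        reversals.to_csv(outdir / "reversals.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — abort names the stage
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "config": dataclasses.asdict(config),
        "inputs": {name: _sha256(path) for name, path in inputs.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
        "stats": stats_out,
        "n_zero_filled": int(n_filled),
        "n_retained_peptides": len(retained),
        "n_excluded_peptides": report.n_excluded,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


__all__ = ["STAGES", "PipelineError", "PipelineConfig", "validate_config", "run_all"]
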