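"""Synthetic cohort generator with planted ground truth.

Emulates the inputs of a post-search metaproteomic study of microbial
proteins in host extracellular-vesicle (bEV) and whole-brain (WB)
proteomes:

* a multi-taxon microbial protein database (random sequences, taxon encoded
  in each header) and a host proteome into which selected microbial tryptic
  fragments are planted — verbatim (host-homologous) or with I<->L swaps
  (host-homologous only up to the I/L ambiguity);
* a taxon annotation table (habitat / pathogenicity / Gram status);
* a study design of 3 subjects per condition, each analyzed in technical
  triplicate, over the Braak-staged groups control, AD3..AD6 plus VaD as an
  off-axis contrast group;
* peptide-level spectral-count tables drawn from a negative-binomial model
  around protein-level group means that follow planted disease trends, with
  missing-at-low-abundance dropout, planted within-group peptide-pair
  correlations (including sign flips between groups) and planted
  anti-correlated bEV<->WB compartment pairs.

Every quantified peptide is recorded in the truth map with its provenance
(microbial_only / host_homologous / host_il_homologous / shared_multiprotein),
every protein with its planted trend, so downstream filters, attribution,
statistics and correlation screens can be checked against construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import build_peptide_index, digest, length_filter, PeptideIndex
from .host_filter import canonicalize_il
from .proteome_db import (
    HOST_TAXON,
    ProteinDatabase,
    ProteinRecord,
    TaxonAnnotation,
    read_fasta,
    read_taxon_annotations,
    write_fasta,
    write_taxon_annotations,
)

GROUPS_BRAAK = ("control", "AD3", "AD4", "AD5", "AD6", "VaD")
GROUPS_PLASMA = ("control", "MCI", "AD")

#: ordinal stage index along the AD axis; VaD is handled off-axis
STAGE_INDEX = {"control": 0, "AD3": 1, "AD4": 2, "AD5": 3, "AD6": 4}

TRENDS = (
    "flat",
    "up_with_stage",
    "down_with_stage",
    "early_peak",
    "vad_only",
    "absent_in_vad",
)

PROVENANCES = (
    "microbial_only",
    "host_homologous",
    "host_il_homologous",
    "shared_multiprotein",
)

#: gene symbols shared across taxa, so one symbol can split into isoforms
#: with distinct disease modulation (the DnaK_1..DnaK_4 situation)
SYMBOL_POOL = (
    "DnaK", "AHCY", "ATPD", "TuF", "SDR", "trxA", "FHS",
    "acnA", "ACAD", "PstS", "GpmA", "Ndk", "TpiA",
)

AA = "ACDEFGHIKLMNPQRSTVWY"
# rough residue frequencies (K/R/L/I boosted a little so tryptic fragments
# and I/L-carrying peptides are plentiful)
AA_WEIGHTS = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 6.8, 7.2, 9.0,
     1.8, 4.4, 5.0, 3.7, 6.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)
AA_WEIGHTS = AA_WEIGHTS / AA_WEIGHTS.sum()


@dataclass
class CorrelationPair:
    feature_a: str
    feature_b: str
    group: str
    r: float


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic bundle."""

    provenance: dict[str, str] = field(default_factory=dict)
    protein_trend: dict[str, str] = field(default_factory=dict)
    peptide_protein: dict[str, str] = field(default_factory=dict)
    correlation_pairs: list[CorrelationPair] = field(default_factory=list)
    compartment_pairs: list[str] = field(default_factory=list)
    protein_fractions: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        pairs = [CorrelationPair(**p) for p in payload.pop("correlation_pairs")]
        return cls(correlation_pairs=pairs, **payload)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

def make_design(
    groups: tuple[str, ...] = GROUPS_BRAAK,
    n_subjects: int = 3,
    n_replicates: int = 3,
    fractions: tuple[str, ...] = ("bEV", "WB"),
) -> pd.DataFrame:
    """Sample sheet: 3 clinical subjects per condition, each fraction
    analyzed in technical triplicate (the study layout being emulated)."""
    rows = []
    for group in groups:
        for s in range(1, n_subjects + 1):
            subject = f"{group}_s{s}"
            for fraction in fractions:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{subject}_{fraction}_r{rep}",
                            "subject_id": subject,
                            "group": group,
                            "fraction": fraction,
                            "replicate": rep,
                        }
                    )
    df = pd.DataFrame(rows)
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return df


# ---------------------------------------------------------------------------
# databases
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length, p=AA_WEIGHTS))


def _plantable_fragments(record: ProteinRecord, need_il: bool = False) -> list[str]:
    """Tryptic 0-missed fragments of a protein suitable for planting:
    inside the 7-22 window, X-free, K/R-terminated, not P-initial."""
    frags = [
        p.sequence
        for p in length_filter(digest(record, max_missed=0))
        if "X" not in p.sequence
        and p.sequence[-1] in "KR"
        and p.sequence[0] != "P"
    ]
    if need_il:
        frags = [f for f in frags if any(c in "IL" for c in f)]
    return frags


def _splice_after_cleavage_site(
    rng: np.random.Generator, target: str, fragment: str
) -> str:
    """Insert ``fragment`` immediately after a K/R cleavage site of
    ``target`` so that tryptic digestion recovers the fragment exactly."""
    sites = [
        i + 1
        for i in range(len(target) - 1)
        if target[i] in "KR" and target[i + 1] != "P"
    ]
    if not sites:
        raise ValueError("target has no usable cleavage site for planting")
    pos = int(rng.choice(sites))
    return target[:pos] + fragment + target[pos:]


def make_databases(
    n_taxa: int = 20,
    proteins_per_taxon: int = 5,
    host_size: int = 60,
    seed: int = 0,
    mean_protein_length: int = 240,
    n_host_homolog_plants: int = 8,
    n_il_homolog_plants: int = 8,
    n_shared_plants: int = 10,
) -> tuple[ProteinDatabase, ProteinDatabase]:
    """Random microbial and host databases with planted homologies.

    A configurable number of microbial tryptic fragments is copied into host
    proteins verbatim, another set with one or more I<->L swaps, and a third
    set into proteins of *other* taxa (creating shared, non-unique
    peptides). Deterministic under ``seed``.
    """
    if min(n_taxa, proteins_per_taxon, host_size) < 1:
        raise ValueError("all database sizes must be >= 1")
    rng = np.random.default_rng(seed)

    microbial_records: list[ProteinRecord] = []
    for t in range(1, n_taxa + 1):
        taxon = f"Tax{t:03d}"
        for j in range(proteins_per_taxon):
            length = int(max(60, rng.normal(mean_protein_length, 50)))
            symbol = SYMBOL_POOL[j % len(SYMBOL_POOL)]
            microbial_records.append(
                ProteinRecord(
                    accession=f"M{t:03d}_{j:02d}",
                    sequence=_random_sequence(rng, length),
                    taxon_id=taxon,
                    gene_symbol=symbol,
                    description=f"synthetic {symbol} of {taxon}",
                )
            )

    host_seqs = {
        f"H{h:04d}": _random_sequence(
            rng, int(max(80, rng.normal(mean_protein_length * 1.5, 80)))
        )
        for h in range(1, host_size + 1)
    }

    # --- plant shared peptides across taxa (done before host planting so
    # the shared copy can itself become host-homologous only by accident,
    # which the final provenance labeling resolves anyway)
    seqs = {r.accession: r.sequence for r in microbial_records}
    meta = {r.accession: r for r in microbial_records}
    donors = list(seqs)
    for _ in range(n_shared_plants):
        for _attempt in range(20):
            donor = str(rng.choice(donors))
            frags = _plantable_fragments(_dc_replace(meta[donor], sequence=seqs[donor]))
            if not frags:
                continue
            frag = str(rng.choice(frags))
            others = [
                a for a in donors
                if meta[a].taxon_id != meta[donor].taxon_id
            ]
            target = str(rng.choice(others))
            try:
                seqs[target] = _splice_after_cleavage_site(
                    rng, seqs[target], frag
                )
            except ValueError:
                continue
            break

    # --- plant host homologs (verbatim) and I/L homologs (swapped)
    host_ids = list(host_seqs)

    def _plant_into_host(fragment: str) -> None:
        hid = str(rng.choice(host_ids))
        seq = host_seqs[hid]
        pos = int(rng.integers(1, len(seq)))
        host_seqs[hid] = seq[:pos] + fragment + seq[pos:]

    for _ in range(n_host_homolog_plants):
        for _attempt in range(20):
            donor = str(rng.choice(donors))
            frags = _plantable_fragments(_dc_replace(meta[donor], sequence=seqs[donor]))
            if not frags:
                continue
            _plant_into_host(str(rng.choice(frags)))
            break

    for _ in range(n_il_homolog_plants):
        for _attempt in range(40):
            donor = str(rng.choice(donors))
            frags = _plantable_fragments(
                _dc_replace(meta[donor], sequence=seqs[donor]), need_il=True
            )
            if not frags:
                continue
            frag = str(rng.choice(frags))
            il_pos = [i for i, c in enumerate(frag) if c in "IL"]
            n_swap = int(rng.integers(1, len(il_pos) + 1))
            swap_at = rng.choice(il_pos, size=n_swap, replace=False)
            chars = list(frag)
            for i in swap_at:
                chars[i] = "L" if chars[i] == "I" else "I"
            swapped = "".join(chars)
            if swapped == frag:
                continue
            _plant_into_host(swapped)
            break

    microbial = ProteinDatabase(
        records=[
            ProteinRecord(
                accession=r.accession,
                sequence=seqs[r.accession],
                taxon_id=r.taxon_id,
                gene_symbol=r.gene_symbol,
                description=r.description,
            )
            for r in microbial_records
        ],
        kind="microbial",
    )
    host = ProteinDatabase(
        records=[
            ProteinRecord(
                accession=hid,
                sequence=host_seqs[hid],
                taxon_id=HOST_TAXON,
                gene_symbol="",
                description="synthetic host protein",
            )
            for hid in host_ids
        ],
        kind="host",
    )
    return microbial, host


def label_provenance(
    index: PeptideIndex, host: ProteinDatabase
) -> dict[str, str]:
    """Final-state provenance of every indexed microbial peptide.

    Labels are computed on the *emitted* databases (after all planting), so
    even accidental homologies are recorded correctly. Host labels dominate
    the shared label.
    """
    host_plain = [rec.sequence for rec in host]
    host_canon = [canonicalize_il(s) for s in host_plain]
    labels: dict[str, str] = {}
    for pep in index:
        canon = canonicalize_il(pep)
        in_canon = any(canon in s for s in host_canon)
        if in_canon:
            if any(pep in s for s in host_plain):
                labels[pep] = "host_homologous"
            else:
                labels[pep] = "host_il_homologous"
        elif len(index.proteins(pep)) > 1:
            labels[pep] = "shared_multiprotein"
        else:
            labels[pep] = "microbial_only"
    return labels


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def make_annotations(
    taxa: list[str] | set[str], seed: int = 0
) -> dict[str, TaxonAnnotation]:
    """Random taxon annotations with proportions echoing the emulated
    cohort's observed breakdowns (76% oral; 32% disease-associated / 24%
    opportunistic; 61% Gram-negative)."""
    rng = np.random.default_rng(seed)
    annotations = {}
    for taxon in sorted(taxa):
        habitat = rng.choice(["oral", "gut", "other"], p=[0.76, 0.08, 0.16])
        patho = rng.choice(
            ["disease_associated", "opportunistic", "health_associated"],
            p=[0.32, 0.24, 0.44],
        )
        gram = rng.choice(["negative", "positive"], p=[0.61, 0.39])
        annotations[taxon] = TaxonAnnotation(taxon, str(habitat), str(patho), str(gram))
    return annotations


# ---------------------------------------------------------------------------
# count model
# ---------------------------------------------------------------------------

def trend_mean(trend: str, group: str, base: float, effect_size: float) -> float:
    """Expected protein-level spectral count for one group under a trend."""
    if trend not in TRENDS:
        raise ValueError(f"unknown trend {trend!r}")
    if group == "VaD":
        if trend == "vad_only":
            return base * effect_size
        if trend == "absent_in_vad":
            return 0.0
        return base
    stage = STAGE_INDEX.get(group)
    if stage is None:
        raise ValueError(f"group {group!r} incompatible with trend model")
    if trend == "flat":
        return base
    if trend == "up_with_stage":
        return base * effect_size**stage
    if trend == "down_with_stage":
        return base * effect_size ** (-stage)
    if trend == "early_peak":
        return base * effect_size if group == "AD3" else base
    if trend == "vad_only":
        return 0.0
    if trend == "absent_in_vad":
        return base
    raise AssertionError(trend)


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts (Poisson when dispersion ~ 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if dispersion <= 1e-9:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_protein_counts(
    trends: dict[str, str],
    design: pd.DataFrame,
    effect_size: float = 2.0,
    dropout_rate: float = 0.1,
    seed: int = 0,
    dispersion: float = 0.3,
    base_mean: float = 30.0,
    fraction: str | None = None,
) -> pd.DataFrame:
    """Protein x sample count matrix (NaN where dropped out).

    The protein-level core of the generator, also usable directly for
    calibration studies (null matrices, power analyses) without building
    sequence databases.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if fraction is not None:
        design = design[design["fraction"] == fraction]
    samples = design["sample_id"].tolist()
    groups = design["group"].tolist()
    proteins = list(trends)
    bases = {
        acc: float(np.exp(rng.normal(np.log(base_mean), 0.4)))
        for acc in proteins
    }
    mat = np.zeros((len(proteins), len(samples)))
    for i, acc in enumerate(proteins):
        means = np.array(
            [trend_mean(trends[acc], g, bases[acc], effect_size) for g in groups]
        )
        mat[i] = _nb_draw(rng, means, dispersion)
    df = pd.DataFrame(mat, index=proteins, columns=samples)
    _apply_dropout(df, dropout_rate, rng)
    return df


def _apply_dropout(
    df: pd.DataFrame, dropout_rate: float, rng: np.random.Generator
) -> None:
    """Missing-at-low-abundance: per-feature dropout probability decreases
    with the feature's mean rank, averaging to ``dropout_rate`` overall."""
    if dropout_rate <= 0:
        return
    means = df.mean(axis=1, skipna=True)
    ranks = means.rank(method="average", pct=True)
    p_miss = (dropout_rate * 2.0 * (1.0 - ranks)).clip(0, 0.95)
    mask = rng.random(df.shape) < p_miss.to_numpy()[:, None]
    df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns), inplace=True)


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    microbial: ProteinDatabase
    host: ProteinDatabase
    annotations: dict[str, TaxonAnnotation]
    design: pd.DataFrame
    quant: pd.DataFrame  # long form: peptide, protein, sample_id, count
    truth: SyntheticTruth


def _assign_trends(
    proteins: list[str], rng: np.random.Generator
) -> dict[str, str]:
    weights = {
        "flat": 0.50,
        "up_with_stage": 0.125,
        "down_with_stage": 0.125,
        "early_peak": 0.10,
        "vad_only": 0.075,
        "absent_in_vad": 0.075,
    }
    names = list(weights)
    p = np.array([weights[n] for n in names])
    draws = rng.choice(names, size=len(proteins), p=p)
    return {acc: str(t) for acc, t in zip(proteins, draws)}


def make_quant_tables(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    effect_size: float = 2.0,
    dropout_rate: float = 0.1,
    seed: int = 0,
    dispersion: float = 0.3,
    base_mean: float = 30.0,
    latent_sigma: float = 0.25,
) -> pd.DataFrame:
    """Long-form peptide x sample spectral counts for every design sample.

    Counts follow a negative binomial around protein-level group means set
    by the planted trend; each peptide carries a fixed share of its
    protein's abundance. Planted correlation pairs override the noise model
    within their group with a shared bivariate-normal latent factor mapped
    through a lognormal link, and planted compartment pairs receive
    anti-correlated bEV/WB latents. Dropout marks cells missing
    ("not detected"), preferentially at low abundance.
    """
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must be in [0, 1)")
    for g in design["group"].unique():
        trend_mean("flat", g, 1.0, effect_size)  # raises on bad group
    rng = np.random.default_rng(seed)

    peptides = sorted(truth.peptide_protein)
    proteins = sorted(set(truth.peptide_protein.values()))
    by_protein: dict[str, list[str]] = {acc: [] for acc in proteins}
    for pep in peptides:
        by_protein[truth.peptide_protein[pep]].append(pep)

    bases = {
        acc: float(np.exp(rng.normal(np.log(base_mean), 0.4)))
        for acc in proteins
    }
    # fixed per-peptide share of the parent protein's abundance
    shares: dict[str, float] = {}
    for acc in proteins:
        peps = by_protein[acc]
        w = rng.gamma(4.0, 1.0, size=len(peps))
        w = w / w.sum()
        for pep, wi in zip(peps, w):
            shares[pep] = float(wi)

    samples = design["sample_id"].tolist()
    sample_group = dict(zip(design["sample_id"], design["group"]))
    sample_fraction = dict(zip(design["sample_id"], design["fraction"]))
    fractions = list(dict.fromkeys(design["fraction"]))

    compartment_set = set(truth.compartment_pairs)
    # per-(subject, replicate, group) latent for compartment pairs
    pair_key = design[["subject_id", "replicate"]].drop_duplicates()
    comp_latent = {
        (row.subject_id, row.replicate): float(rng.normal())
        for row in pair_key.itertuples()
    }
    sample_comp_latent = {
        row.sample_id: comp_latent[(row.subject_id, row.replicate)]
        for row in design.itertuples()
    }

    n_pep, n_s = len(peptides), len(samples)
    mat = np.full((n_pep, n_s), 0.0)
    pep_pos = {p: i for i, p in enumerate(peptides)}

    for acc in proteins:
        trend = truth.protein_trend.get(acc, "flat")
        frs = truth.protein_fractions.get(acc, fractions)
        for j, s in enumerate(samples):
            g = sample_group[s]
            fr = sample_fraction[s]
            mu = trend_mean(trend, g, bases[acc], effect_size) if fr in frs else 0.0
            if acc in compartment_set and mu > 0:
                sign = 1.0 if fr == fractions[0] else -1.0
                u = sample_comp_latent[s]
                det = mu * np.exp(sign * 0.3 * u)
                for pep in by_protein[acc]:
                    mat[pep_pos[pep], j] = np.round(det * shares[pep] * len(by_protein[acc]))
            else:
                for pep in by_protein[acc]:
                    m = mu * shares[pep] * len(by_protein[acc])
                    mat[pep_pos[pep], j] = _nb_draw(
                        rng, np.array([m]), dispersion
                    )[0]

    # planted within-group correlations: overwrite counts of the pair's
    # features in that group with a shared latent factor realization
    for pair in truth.correlation_pairs:
        idx = [
            j for j, s in enumerate(samples)
            if sample_group[s] == pair.group
            and sample_fraction[s] == fractions[0]
        ]
        if not idx:
            continue
        rho = float(np.clip(pair.r, -0.999, 0.999))
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=len(idx))
        for which, feat in enumerate((pair.feature_a, pair.feature_b)):
            acc = truth.peptide_protein[feat]
            m = bases[acc] * shares[feat] * len(by_protein[acc])
            m = max(m, 50.0)  # keep rounding noise negligible
            vals = np.round(m * np.exp(latent_sigma * z[:, which]))
            mat[pep_pos[feat], idx] = vals

    df = pd.DataFrame(mat, index=peptides, columns=samples)
    _apply_dropout(df, dropout_rate, rng)

    long = df.reset_index(names="peptide").melt(
        id_vars="peptide", var_name="sample_id", value_name="count"
    )
    long["protein"] = long["peptide"].map(truth.peptide_protein)
    return long[["peptide", "protein", "sample_id", "count"]]


def make_bundle(
    n_taxa: int = 20,
    proteins_per_taxon: int = 5,
    host_size: int = 60,
    effect_size: float = 2.0,
    dropout_rate: float = 0.1,
    seed: int = 0,
    n_correlation_pairs: int = 4,
    n_signflip_pairs: int = 3,
    n_compartment_pairs: int = 4,
    max_peptides_per_protein: int = 4,
    groups: tuple[str, ...] = GROUPS_BRAAK,
    fractions: tuple[str, ...] = ("bEV", "WB"),
    dispersion: float = 0.3,
) -> SyntheticBundle:
    """Generate the complete input set with a coherent truth map."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    microbial, host = make_databases(
        n_taxa=n_taxa,
        proteins_per_taxon=proteins_per_taxon,
        host_size=host_size,
        seed=seed,
    )
    index = build_peptide_index(microbial)
    provenance = label_provenance(index, host)

    design = make_design(groups=groups, fractions=fractions)
    annotations = make_annotations(microbial.taxa, seed=seed)

    # choose quantified peptides: a handful per protein (preferring unique
    # ones) plus every host-homologous peptide, so the host filter always
    # has planted positives to act on
    by_protein: dict[str, list[str]] = {}
    for pep in index:
        for acc in index.proteins(pep):
            by_protein.setdefault(acc, []).append(pep)
    peptide_protein: dict[str, str] = {}
    for acc in sorted(by_protein):
        peps = sorted(by_protein[acc])
        unique_first = sorted(
            peps,
            key=lambda p: (len(index.proteins(p)) != 1, p),
        )
        chosen = unique_first[:max_peptides_per_protein]
        chosen += [
            p for p in peps
            if provenance[p]
            in ("host_homologous", "host_il_homologous", "shared_multiprotein")
        ]
        for pep in chosen:
            # a shared peptide is driven by one (arbitrary but fixed) parent
            peptide_protein.setdefault(pep, acc)

    trends = _assign_trends(sorted(by_protein), rng)

    # compartment partition: most proteins in both fractions, some exclusive
    protein_fractions: dict[str, list[str]] = {}
    if len(fractions) >= 2:
        for acc in sorted(by_protein):
            u = rng.random()
            if u < 0.10:
                protein_fractions[acc] = [fractions[0]]
            elif u < 0.20:
                protein_fractions[acc] = [fractions[1]]
            else:
                protein_fractions[acc] = list(fractions)
    else:
        protein_fractions = {acc: list(fractions) for acc in sorted(by_protein)}

    # planted peptide-pair correlations among peptides of flat, both-fraction
    # proteins (so the trend model does not confound the planted r)
    flat_peps = sorted(
        p for p, acc in peptide_protein.items()
        if trends[acc] == "flat"
        and len(protein_fractions[acc]) == len(fractions)
        and provenance[p] == "microbial_only"
    )
    rng.shuffle(flat_peps)
    pairs: list[CorrelationPair] = []
    cursor = 0
    for _ in range(n_correlation_pairs):
        if cursor + 1 >= len(flat_peps):
            break
        a, b = flat_peps[cursor], flat_peps[cursor + 1]
        cursor += 2
        pairs.append(CorrelationPair(a, b, "control", 0.9))
    for _ in range(n_signflip_pairs):
        if cursor + 1 >= len(flat_peps):
            break
        a, b = flat_peps[cursor], flat_peps[cursor + 1]
        cursor += 2
        pairs.append(CorrelationPair(a, b, "control", 0.8))
        pairs.append(CorrelationPair(a, b, groups[1], -0.8))

    # planted anti-correlated compartment proteins: flat, in both fractions
    flat_prot = [
        acc for acc in sorted(by_protein)
        if trends[acc] == "flat"
        and len(protein_fractions[acc]) == len(fractions)
        and not any(
            truth_pep in (p.feature_a, p.feature_b)
            for p in pairs
            for truth_pep in by_protein[acc]
            if truth_pep in peptide_protein
        )
    ]
    rng.shuffle(flat_prot)
    compartment_pairs = flat_prot[:n_compartment_pairs]

    truth = SyntheticTruth(
        provenance={p: provenance[p] for p in peptide_protein},
        protein_trend=trends,
        peptide_protein=peptide_protein,
        correlation_pairs=pairs,
        compartment_pairs=compartment_pairs,
        protein_fractions=protein_fractions,
        seed=seed,
    )
    quant = make_quant_tables(
        truth,
        design,
        effect_size=effect_size,
        dropout_rate=dropout_rate,
        seed=seed,
        dispersion=dispersion,
    )
    return SyntheticBundle(microbial, host, annotations, design, quant, truth)


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "microbial": outdir / "microbial.fasta",
        "host": outdir / "host.fasta",
        "annotations": outdir / "annotations.tsv",
        "peptides": outdir / "peptides.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(bundle.microbial, paths["microbial"])
    write_fasta(bundle.host, paths["host"])
    write_taxon_annotations(bundle.annotations, paths["annotations"])
    quant = bundle.quant.copy()
    quant["count"] = quant["count"].astype("Int64")
    quant.to_csv(paths["peptides"], sep="\t", index=False)
    bundle.design.to_csv(paths["design"], sep="\t", index=False)
    bundle.truth.to_json(paths["truth"])
    return paths


def read_bundle(outdir: str | Path) -> SyntheticBundle:
    outdir = Path(outdir)
    microbial = read_fasta(outdir / "microbial.fasta", kind="microbial")
    host = read_fasta(outdir / "host.fasta", kind="host")
    annotations = read_taxon_annotations(
        outdir / "annotations.tsv", known_taxa=microbial.taxa
    )
    quant = pd.read_csv(outdir / "peptides.tsv", sep="\t")
    quant["count"] = quant["count"].astype("Float64").astype(float, errors="ignore")
    quant["count"] = pd.to_numeric(quant["count"], errors="coerce")
    design = pd.read_csv(outdir / "design.tsv", sep="\t")
    truth = SyntheticTruth.from_json(outdir / "truth.json")
    return SyntheticBundle(microbial, host, annotations, design, quant, truth)


__all__ = [
    "GROUPS_BRAAK",
    "GROUPS_PLASMA",
    "STAGE_INDEX",
    "TRENDS",
    "PROVENANCES",
    "CorrelationPair",
    "SyntheticTruth",
    "SyntheticBundle",
    "make_design",
    "make_databases",
    "label_provenance",
    "make_annotations",
    "trend_mean",
    "simulate_protein_counts",
    "make_quant_tables",
    "make_bundle",
    "write_bundle",
    "read_bundle",
]
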