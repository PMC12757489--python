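# Methods

## Problem setting

Peptides identified in a host-derived sample (brain extracellular vesicles,
bEV; residual whole-brain tissue, WB; plasma EVs) can be attributed to
microbial proteins only after two hazards are controlled: (i) a peptide
sequence may also occur in the host proteome — and since mass spectrometry
cannot distinguish isoleucine from leucine, "occur" must be assessed over
every I/L variant of the peptide; (ii) a peptide may map to several
proteins or taxa, in which case its spectra cannot be attributed to any one
of them. The pipeline implements the post-search stages that resolve both,
then quantifies, tests, and correlates the surviving signal across disease
stages.

## Digestion and indexing

Trypsin cleaves C-terminally of K or R, suppressed when the next residue is
proline. This plain rule (no W|KP / M|RP exceptions) is applied through
`pyteomics.parser.xcleave` so fragment offsets are tracked. Products with
0..`max_missed` missed cleavages are emitted; `max_missed` defaults to 2, a
common search-engine setting, and is configurable because search parameters
vary between studies. The analysis window is 7–22 residues — shorter
fragments are rarely identifiable, longer ones fall outside the length
range of the identified peptide population being emulated. N-terminal
methionine loss is not modeled. Non-canonical residues (B, Z, X, U, O) are
sanitized to `X` at database read time and any fragment containing `X` is
dropped from the index: such peptides cannot be compared unambiguously
under I/L logic.

I and L are *not* merged in the index. Attribution stays literal to the
database sequences; the ambiguity is handled in exactly one place, the host
filter, so that uniqueness flags always refer to real database entries.

## Host-homology filter

A peptide is excluded iff any of its 2^k I/L variants (k = number of I/L
residues) occurs as a contiguous substring of any host protein. Two
sequences share an I/L variant iff their I→L canonical forms are equal, so
the production path canonicalizes both the peptide and the host text and
performs a single substring search — exact, and linear instead of
exponential in k. The literal 2^k enumeration with a per-protein scan is
retained as the brute-force oracle used by the tests, keeping the two
routes independent.

Substring matching against whole host sequences is the default because it
is the conservative reading of "present in the host proteome": it excludes
a superset of what matching against host *tryptic peptides* would exclude.
The tryptic mode is available (`mode="tryptic"`) for sensitivity analysis.
Peptides containing `X` are excluded with reason "ambiguous residue".

## Attribution and presence

`unique_to_protein` holds iff the peptide has exactly one parent protein in
the database; `unique_to_taxon` iff all parents share one taxon.
Quantification uses protein-level uniqueness (spectra must be unambiguous
at the protein level); organism presence calls use taxon-level uniqueness
(a peptide shared by two proteins of the same organism is still unequivocal
evidence for that organism). A protein or taxon is "common" when detected
(≥ 1 supporting unique peptide with count > 0) in every subject; detection
within a subject pools that subject's technical replicates, since
commonality is a subject-level notion. The restricted-database consistency
operation re-attributes peptides against the sub-database of entries
identified at least once and reports peptides whose uniqueness status
changed; restriction can only shrink parent sets, so a uniqueness loss or a
peptide losing all parents is flagged as an inconsistency.

## Quantification

Protein abundance is the summed spectral count of the protein's unique
peptides (exact integer conservation is asserted: the protein matrix total
equals the unique-peptide total). Two missing-value policies mirror the
primary and validation analysis paths: zero-fill ("not detected" → 0)
before roll-up, and left-censored imputation + log2 for statistical
re-evaluation. The censored-imputation method is deliberately simple and
deterministic by default — zeros become half the row's minimum positive
value — because determinism makes the validation path reproducible; a
stochastic down-shifted Gaussian (shift 1.8 SD, width 0.3 SD in log2
space, seeded) is available as the alternative commonly used in proteomics.
Technical replicates are averaged within subject before group statistics,
so n per group is the number of subjects (3 by default) and replicate runs
do not masquerade as biological replication; a pooled-replicate mode
exists. No between-sample normalization is applied by default.

## Stage-wise statistics

Protein × stage profiles (group means over subjects) are z-scored per
protein and clustered with classic fuzzy c-means: fuzzifier m = 2,
alternating membership/centroid updates until the maximum centroid shift
falls below 1e-6 or 300 iterations, objective asserted non-increasing.
Memberships of one protein sum to 1; proteins whose best membership is
below 0.5 are flagged unretained. The number of clusters defaults to the
k ∈ {2..8} maximizing the fuzzy partition coefficient and can be fixed.
Note one boundary subtlety: the retention rule is "max membership ≥ 0.5",
so a perfectly ambiguous two-cluster protein (membership exactly 0.5) is
retained by the letter of the rule; such degenerate features are visible
through their tied memberships.

Gene symbols whose member proteins land in different clusters are split
into subscripted isoforms (`DnaK_1`, `DnaK_2`, …), with subscripts assigned
by descending first-stage mean — a deterministic order that survives
arbitrary cluster relabeling.

Four test tags run side by side rather than guessing which variant applied
to which feature: one-way ANOVA with Bonferroni-corrected pairwise
contrasts (the primary screen; a feature is significant when the omnibus
and at least one adjusted contrast reach α = 0.05), Fisher's LSD
(unadjusted pairwise p, only after a significant omnibus), one-way ANOVA on
ranks (Kruskal–Wallis), and two-way ANOVA with group and technical
replicate batch as factors — replicate batch being the only plausible
second factor in this design; that choice is an assumption, documented
here. Features with no variance at all are reported with p = 1 and a
degenerate flag. Pairwise contrasts use the pooled ANOVA mean square, and
Bonferroni multiplies within each feature's 15-contrast family. Tiers
(p ≤ 0.05 / 0.01 / 0.001) carry the figure symbols of each family
(∗/∗∗, +/++, #).

Dementia categories are assigned by deterministic precedence: **VaD** when
presence is exclusive to VaD or exclusively absent in VaD (or significance
involves only VaD contrasts); **AD_progression** when stage means are
monotone along control→AD6 (|Spearman ρ| ≥ 0.8) with ≥ 1 significant stage
contrast; **early_AD** when AD3-vs-control is significant or presence is
exclusive to AD3; **AD** for any other significant stage contrast;
**none** otherwise.

## Correlation screens

Pearson r within study groups, p from the t transform, 95% CI by Fisher z.
Strength conventions: strong |r| ≥ 0.70, very strong |r| ≥ 0.85,
significance p ≤ 0.05; the thresholds are applied to |r|, and the
peptide-heatmap filter ("> 0.5 in at least one group") is likewise applied
to |r|. Pairs with fewer than 3 complete observations or zero variance are
reported with flags, never silently dropped. The reversal report lists
pairs with significant r ≥ +0.5 in one group and ≤ −0.5 in another —
the reversed-correlation pattern between controls and early disease.
Cross-compartment correlations pair bEV and WB samples by (subject,
replicate), both fractions deriving from the same specimen, and are
computed per common protein after partitioning features into
bEV-only / WB-only / common by detection. Correlations run on zero-filled
counts by default (the primary quantitation path); an option uses the
censored-imputed log2 matrix.

## Synthetic cohort generator

The generator is the package's test bed and defines the study conditions:
6 groups (control, AD3–AD6, VaD), 3 subjects per condition, technical
triplicates, two fractions (bEV, WB) — 108 samples. Defaults: 20 taxa × 5
proteins (~240-residue random sequences with mildly realistic residue
frequencies), 60 host proteins, 8 verbatim + 8 I/L-swapped host plants, 10
cross-taxon shared plants. Planted fragments are spliced after existing
cleavage sites so digestion recovers them exactly; provenance labels
(microbial_only / host_homologous / host_il_homologous /
shared_multiprotein) are computed on the *final* databases, so even
accidental homologies are labeled correctly.

Counts are negative binomial (dispersion 0.3 — spectral counts are
overdispersed; Poisson available) around protein-level group means that
follow the planted trend: up/down_with_stage multiply the base mean by
`effect_size` per stage step (so effect 2 gives a 16-fold control→AD6
ratio), early_peak elevates AD3 only, vad_only/absent_in_vad make the
protein exclusive to/absent from VaD. Dropout is missing-at-low-abundance:
per-feature dropout probability decreases linearly in the feature's mean
rank and averages to the requested rate. Planted correlation pairs are
realized through a shared bivariate-normal latent factor mapped by a
lognormal link with σ = 0.25 — small enough that the attenuation of the
target r is ≲ 0.01 and the sampling distribution of r stays close to
normal theory; planted compartment pairs share a per-(subject, replicate)
latent with opposite signs in the two fractions.

What the generator does **not** emulate: spectra and search-engine scoring,
retention times, subject-level random effects beyond the group mean,
peptide-level ionization efficiency differences, shared-peptide razor
assignment, and real phylogenetic sequence correlation between taxa
(sequences are i.i.d. random, so cross-taxon homology exists only where
planted). Passing tests therefore demonstrate the correctness of the
pipeline's logic and its statistical calibration under a realistic count
model — not search-engine-level identification performance on real data.

## Problem sizes and numerical choices

Calibration studies run at deliberately modest sizes chosen to estimate
the relevant rates stably: the null screen uses 1000 flat features in one
cohort; power uses 25 non-flat proteins × 50 generator seeds at effect
size 3, dropout 0.1; cluster recovery uses 50 proteins × 20 seeds; the
host-filter oracle comparison uses 10 database pairs with ≥ 1000 candidate
peptides each. Fuzzy c-means uses tolerance 1e-6 on the centroid shift;
correlation CIs return the full [-1, 1] interval when n ≤ 3; ties in
isoform ordering break on cluster id; the acceptance script derives every
sub-seed from the single `--seed` argument.

## Known limitations

* The host filter is exact-occurrence only; mismatch-tolerant homology is
  out of scope by design.
* Protein inference is naive (no parsimony grouping); peptides unique to a
  sequence shared verbatim by several database strains are reported as
  shared, with the collision visible in the attribution table.
* The dementia-category rules are a deterministic reconstruction of a
  figure-level narrative; borderline features (e.g. an early peak whose
  AD3 contrast narrowly misses Bonferroni significance) fall into
  neighboring categories.
* VaD is modeled as a categorical off-axis group; no ordinal relation
  between VaD and the AD stages is assumed anywhere.
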