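# Methods

## Statistical model of the enrichment analysis

The pipeline treats the peptide report as draws from a hierarchical
multiplicative model: protein abundance × peptide response × replicate
noise, with group membership acting only through a per-protein fold
change.  All inference happens at the protein level after rollup:

* **Fold change.** FC = mean(experimental) / mean(control) of the rolled-up
  protein intensities on the linear scale.  The alternative convention —
  back-transforming the mean log2 difference — is available as
  `fc_mode="log_means"`; the two differ under replicate noise because the
  arithmetic mean of a log-normal exceeds its geometric mean.  The linear
  reading is the default because the quantity of interest is a ratio of
  (summed) intensities.
* **Test.** Two-tailed Welch *t*-test on log2 intensities with
  Welch–Satterthwaite degrees of freedom, per protein, assuming
  independence across proteins for the Benjamini–Hochberg step-up.  No
  variance moderation is applied: with 3 replicates per group the test is
  deliberately the plain heteroscedastic one, and power comes from the
  depth of peptide evidence per protein rather than from shrinkage.
* **Call.** `enriched = (FC > 1.5) and (q < 0.05)`, both strict
  inequalities, so values exactly at a threshold are never called.

Degenerate inputs: when both groups have zero variance the p-value is 1
for equal means and 0 otherwise; proteins with a non-positive group mean
are flagged `untestable` (FC undefined) and excluded from the FDR family.
Zeros — which imputation rule 2 legitimately assigns — cannot enter the
log transform and are replaced, for the test only, by half the smallest
positive value in the normalized matrix; linear-scale means (and hence
FC) use the true zeros.

## Imputation

Imputation works per peptide × biological group, with the detection mask
of originally measured cells preserved and never altered:

1. If the fraction of missing values in the group is **below 0.5**, each
   missing cell is drawn from a Normal whose mean and SD are the empirical
   moments of all measured values in the peptide's intensity bin.  Bins
   are 20 equal-width bins on log10 intensity spanning all measured
   values (a `linear` bin scale is available as a config switch); the
   peptide's bin comes from its within-group measured mean.  Bins with
   fewer than 3 values are pooled with nearest neighbours.  Negative
   draws are redrawn (and clipped at 0 after 1000 attempts) — intensity
   is non-negative, and with MS-scale means the truncation is
   negligible.
2. If **strictly more than half** of the group is missing and the
   peptide's reference intensity exceeds 5×10⁶, the group's missing cells
   are set to 0: an otherwise-intense peptide absent from most of a group
   is read as genuinely absent there.  The reference intensity is the
   within-group mean of measured values (falling back to the all-sample
   mean when the group has none); group maximum and global mean are
   config options, since the export format this rule originates from does
   not pin the statistic down.  A group missing exactly half its values
   satisfies neither condition 1 nor condition 2 and falls through to
   rule 3.
3. Every still-missing cell is drawn uniformly from the pool of the
   lowest 2% of all measured values (`floor(0.02 · n)` smallest, at least
   one).  Drawing from the pool rather than imputing a constant avoids
   degenerate zero-variance groups.

All draws come from one generator seeded by `ImputationParams.seed` and
recorded in the run manifest.

The occurrence filter runs *after* imputation but is evaluated on the
pre-imputation mask: "measured" can only refer to real detections.  A
peptide is kept when it has ≥ 2 detections overall and detections in
≥ 50% of the replicates of at least one group.

## Normalization

Total-intensity scaling followed by 10% two-sided trimmed-mean scaling.
Both stages multiply each sample by one positive factor so the sample's
statistic (column total; trimmed mean) equals the grand mean of that
statistic over samples.  Trim counts use `floor(n · trim)` values removed
at each tail, per sample; assigned zeros participate as the value 0.  The
grand-mean anchor makes both stages exactly idempotent and symmetric in
the samples.  One consequence worth stating: rescaling a single input
sample rescales the *anchor* too, so outputs before and after such a
rescaling agree up to one global factor (identical normalized structure),
not cell-for-cell — the relevant invariant, since only relative
intensities carry meaning downstream.

## Network, phosphopeptides, kinase gating

Network nodes are the enriched proteins, gene-labelled.  External edges
(STRING-style, scores auto-rescaled from the 0–1000 dialect when needed)
are kept between two enriched nodes at combined score ≥ 0.7.  The data
itself carries only one kind of interaction evidence — proximity
biotinylation — so "in-data" edges are implemented as bait→prey edges
from the bait node to enriched proteins with a directly detected
biotinylated peptide; this is a documented stand-in for an otherwise
under-defined notion and can be disabled
(`include_bait_edges=False`).

Phosphopeptides are quantified by the same pipeline and gated at the
peptide level with the same FC/q thresholds, then narrowed in three
nested stages: all phosphopeptides → enriched → on proteins with
biotinylated-peptide evidence.  Nesting is asserted on every run.

Kinase–substrate gating scores a −5..+4 window around each
phosphoacceptor against per-kinase log-odds matrices (window
configurable; this is the convention of published kinase-specificity
atlases).  Windows reaching past the protein termini are padded with a
neutral symbol scoring 0.  The percentile of a site is the percentage of
background sites scoring *strictly below* it (min-rank tie handling —
conservative for a strict "> 90" gate), and only pairs above the cutoff
are emitted.

## Behavioral scoring and morphometry

Consecutive duplicate arm entries are collapsed at ingest: an entry
requires leaving and re-entering.  Radial-arm errors are re-entries into
any arm already visited in the session (the memory never resets within a
session).  Y-maze alternations are overlapping windows of three
consecutive entries into three distinct arms, divided by entries − 2 —
the overlapping-window reading is forced by that printed denominator.
DNMTP correct-choice percentages are excluded for days with ≥ 5 failed
forced trials.  Undefined quantities (latency to an error that never
happened; alternation of a session with < 3 entries) are NaN sentinels,
never 0.

`compare_groups` gates on Shapiro–Wilk normality (α = 0.05) per group:
both normal → unpaired *t*-test (classical pooled by default, Welch as a
switch — note the proteomics module always uses the heteroscedastic
test); otherwise Mann–Whitney for behavioral data or two-sample
Kolmogorov–Smirnov for morphometry distributions.  Constant groups have
undefined normality and fall to the nonparametric branch.

`rout_outliers` implements robust outlier removal for the univariate
(constant-model) case: location = median, scale = the 68.27th percentile
of absolute residuals (a robust SD analogue), residual *t*-scores
converted to two-tailed p-values (n − 1 df) and tested with a
Benjamini–Hochberg step-up at the requested maximum FDR (1% default);
below 5 points nothing is flagged.  This is an approximation to the
proprietary implementation found in commercial statistics packages; its
test surface is calibration (false-flag rate ≤ ~2% on clean Normal data
at n = 10), not value matching.

## The synthetic-data generator

`simulate_peptide_report` emulates a DIA precursor export: protein
baselines log10-Normal(`log_mean_intensity` = 6.0, sd 0.6), peptide
offsets log10-Normal(0, 0.4), replicate noise log-normal with CV
`cv_within_group` (15% default), peptides split over one or two charge
states with Dirichlet weights.  Spiked proteins multiply only
experimental-group intensities by `spike_fc`; contaminants
(keratin/avidin analogues plus a non-target-species share) are
group-independent and never spiked.  Dropout is the union of a logistic
MNAR term in log10 intensity and an independent MCAR Bernoulli.

Defaults the source experiment does not pin down were chosen once for
realism and are not fitted to any data:

| parameter | default | rationale |
|---|---|---|
| `peptides_per_protein` | (8, 18) | matches the observed depth of the assay (~44,000 peptides over ~3,325 proteins ≈ 13/protein) |
| `cv_within_group` | 0.15 | typical label-free between-replicate CV |
| `spike_fraction` | 0.04 | bait-specific enrichment is rare (19 of 3,325 proteins in the motivating dataset); 4% of 500 proteins keeps ~20 spikes for stable recall statistics |
| `dropout_mnar_midpoint` | 1×10⁴ | detection limit two orders below the typical peptide |
| `dropout_mnar_slope` | 4.0 /log10 | DIA missingness is sharply intensity-dependent; yields ~5% overall missingness at the defaults |
| `dropout_mcar_rate` | 0.01 | small random-loss floor |
| `contaminant_fraction` | 0.05 | typical share of keratin/avidin/foreign entries |
| `frac_biotinylated` | 0.01 per peptide | ≈ 4% of proteins with direct biotinylation evidence, matching the assay's observed rate |
| `frac_phospho` | 0.011 | matches the observed phosphopeptide share (495 of ~44,000) |

The generator reproduces the *statistical structure* the rules
distinguish (MNAR vs MCAR regimes, mostly-missing intense peptides,
low-tail censoring, contaminant removal, spike recovery) but not real
chromatographic artefacts, interference, shared/razor peptides, batch
effects, or correlated noise across peptides of a protein.  Passing tests
therefore certify the implementation of the procedure and its operating
characteristics under the assumed model — not performance on any real
acquisition.

`simulate_entry_sequence` draws maze entries where, with probability
`p_alternate`, the next arm is uniform among arms not visited in the last
`n_arms − 1` entries, else uniform among recently visited arms other than
the current one.  For a 3-arm maze this makes each overlapping 3-window
an alternation with probability exactly `p_alternate`, so 0.5 is the
chance level; 1.0 forces perfect alternation.

## Problem sizes and numerical tolerances

The test and acceptance workloads use 500 proteins × 3 vs 3 replicates
(the design size of the motivating study) for error-rate and recovery
checks: 200 null replicates for the realized false-discovery proportion
and 5 spike replicates (~95 spiked proteins) for recall; the Y-maze
chance-level check uses 10,000 sessions of 50 entries; the imputation
rule-1 distribution check uses 10,000 draws against the target bin's
Normal (two-sample KS at α = 0.01).  Oracle agreement is required to
1e-10 (Welch p-values vs the closed form) and 1e-12 (BH vs brute-force
step-up); normalization idempotence to 1e-9 relative.

## Known limitations

* Protein grouping/razor-peptide assignment is upstream of the exported
  report and out of scope; a sequence mapped to two proteins is an error,
  not a grouping problem to solve.
* FDR control is inherited from Benjamini–Hochberg under the simulated
  independence across proteins; correlated proteins (complexes) would
  make the realized proportion less predictable.
* The bait→prey "in-data" edge rule is a stand-in (see above), and
  phosphosite localization probabilities are taken as given.
* Composition effects are real: with a non-trivial spiked mass fraction,
  total-intensity/trimmed-mean normalization absorbs part of the spike,
  biasing estimated fold changes slightly toward 1 (visible as median
  estimated FC ≈ 3.7–3.8 for a true 4-fold spike at the defaults).
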