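# Methods

## Virtual population

Each marginal (age, BMI, per-sex height) is a truncated normal. Bounds
exclude impossible adults: age ∈ [18, 90] y, BMI ∈ [15, 60] kg/m², height
within ±4 sd of its per-sex mean. For age and BMI the *location* of the
truncated normal is calibrated by root finding so the truncated
distribution's mean equals the printed target mean — naive truncation of
N(45.53, 13.23) at 18 y would shift the generated mean up by ~0.6 y, making
the population systematically older than the reference it must reproduce.
Heights use configurable European per-sex defaults (male 177.6 ± 7.0 cm,
female 164.6 ± 6.5 cm); these are configuration values, not literature
claims.

Weight is never sampled: it is derived as BMI · height(m)², which makes the
BMI–weight–height identity exact for every patient. The weight marginal is
then matched by an acceptance loop that redraws the continuous covariates
until the sample mean is within 0.5·SE(mean) and the sample sd within
0.5·SE(sd) of the targets (SE(sd) ≈ sd/√(2n); budget 10,000 redraws, ~10
needed at n = 500). Two consequences worth knowing:

- The targets are mildly inconsistent: independent BMI × height² implies a
  mean weight ≈ 1 kg above the printed weight target, so the loop's
  selection nudges the realized BMI mean down by ~0.3 kg/m² (well inside the
  BMI target's 3 SE band at n = 500). At much larger n the shrinking SE makes
  the window unreachable and the generator fails explicitly, naming the
  violated marginal.
- Sex is drawn once per seed, *outside* the loop. Resampling sex inside the
  loop would let the acceptance condition select high-female samples (shorter
  patients lower the weight mean) and bias the realized sex ratio.

Comorbidity tags are independent Bernoulli draws per tag (no co-occurrence
model). Obesity is granted only to patients with BMI > 30; its per-eligible
probability is inflated so the population frequency matches the request, and
an unrealizable request (frequency above the eligible fraction) is an error.
The type-II diabetes default frequency is 4.38% (a 15-patient cohort then
needs ⌈15/0.0438⌉ = 343 subjects); other prevalence defaults are
placeholders to be replaced with real-world inputs.

Validation uses the unpaired two-tailed Welch t-test against the
reconstructed reference summary (mean/sd/n), an exact binomial test for the
sex ratio, and Wilcoxon rank-sum tests for comparing two simulated
populations.

## Pharmacokinetics

The model is linear and non-stiff: a first-order skin depot feeding a
central blood compartment with first-order elimination. Units are days, mg,
L, mg/L; the default grid step is 0.1 day and dose events must fall on grid
points. Subcutaneous and oral doses enter the depot scaled by bioavailability
f_bio (default 1.0 — unknown for this drug and exposed as configuration);
intravenous doses enter the central compartment directly, which also covers
the single-compartment iv reference drug. ka = kel is a removable singularity
of the Bateman form and is perturbed by 1e-9.

The default simulation path is the exact closed-form Bateman superposition;
a fixed-step RK4 integrator is provided and agrees with the closed form to
~1e-8 relative on the default grid (the tests require 1e-6). Mass balance
(depot + central + eliminated vs dosed) closes to 0.1%.

Individualization: central volume from an allometric sex/height/weight
formula (male 0.3669·h³ + 0.03219·w + 0.6041 L, female
0.3561·h³ + 0.03308·w + 0.1833 L, h in m, w in kg), times a configurable
distribution-volume adjustment factor (default 1.0) because a biologic's
apparent distribution volume can exceed plasma volume; depot volume scales
with Du Bois body surface area. The reference patient is 75 kg / 170 cm /
40 y (V_blood 4.821 L); reference rates are ka from Tmax ≈ 5 d via the
Tmax/3 rule and kel from a 14-day terminal half-life. The contract is the
scaling behavior, not the constants — all are overridable.

kel fitting minimizes the sum of squared concentration residuals with a
bounded scalar optimizer over [1e-3, 1] /day and reports R² and residuals;
non-identifiable inputs (a single observation time) are rejected.

## Synthetic protein activities

The generator emulates per-patient, per-protein predicted activities in
[−1, 1] so the scoring/clustering/enrichment stages are testable without the
proprietary systems-biology engine. Generative model per patient-arm:
baseline activity +v_i (each effector at its pathological sign); the drug
pulls every effector toward 0 by a Hill fraction
emax·C^h/(EC50^h + C^h) of baseline (defaults emax 0.9, EC50 10 mg/L,
h = 1; the exposure summary is the mean concentration over weeks 12–16,
configurable to Cmax or AUC); per-group offsets of magnitude δ with a seeded
{−1, 0, +1} protein pattern encode comorbidity-driven mechanistic groups;
additive Gaussian noise; then a smooth tanh squash into [−1, 1] (clipping
available). Everything is deterministic under a seed.

What this does *not* emulate: real protein–protein interaction topology,
network propagation, or any quantitative relation between specific proteins
and severity — passing tests demonstrate that the pipeline recovers structure
that is present, not that real psoriasis biology has that structure.

The reference-drug panel ties exposure to efficacy: each drug's true signal
is 1 − Hill(exposure) and PASI75 = A·tSignal + B (+ optional noise), anchored
at a 5% placebo level, so the calibration regression can recover the
generating (A, B) exactly at zero noise. PASI75 inputs given as percentages
are divided by 100.

The planted-distorter panel (for pruning tests) makes the non-distorter
proteins carry the drug's latent signal exactly while distorter "junk"
vectors are mutually orthonormal and orthogonal to both the signal and the
constant, scaled to sd 0.5 within [−1, 1]. This guarantees each distorter
strictly degrades the tSignal–efficacy correlation, so the planted set is
exactly identifiable — with unconstrained random junk it would not be.

## tSignal scoring and calibration

tSignal averages sign-weighted activities over the effectors with non-zero
signal; n counts only those (a silent protein neither supports nor
contradicts the disease state). A fixed-denominator variant is available
behind a flag; an all-zero signal vector is an explicit error. Calibration is
ordinary least squares with Pearson ρ.

Definition pruning is greedy best-first: discard the protein whose removal
most increases |ρ|, ties broken lexicographically, stopping at a minimum set
size or when the best gain falls below a floor (default 5e-5 on |ρ|). The
floor matters: an unconditional greedy chases sampling noise and can discard
~20% of a clean panel. Measured gain profiles separate the regimes —
removing a genuinely distorting protein raises |ρ| by ≳1e-4 at the
124-protein definition scale, while noise-chasing gains stay below 5e-5 —
so the floor preserves curated molecular information, which is the stated
purpose of the calibration step.

Severity-marker analysis reports per-arm Pearson ρ of each marker's activity
against the per-model tSignal with Benjamini–Hochberg q-values; the strength
band (strong |ρ| > 0.8; moderate 0.5–0.8; low 0.3–0.5; negligible ≤ 0.3) is
assigned from the weaker of the two arms, i.e. the band that holds for both
dosing schemes.

## Clustering

Per-arm centering subtracts each protein's arm mean, removing the direct
dose/exposure offset between arms while preserving within-arm variability
(the alternative — per-row centering — is not implemented as the default;
per-protein-within-arm is the reading adopted). Reduction is PCA or
*classical* (Torgerson) MDS on Euclidean or 1 − Spearman row distance;
classical MDS is implemented directly because it is exact on distances that
are Euclidean in the target dimension, which the tests exploit. Constant
rows have no rank correlation and are rejected by name.

Algorithms: scikit-learn k-means, spectral, Gaussian mixture and
agglomerative (average/complete/ward on Euclidean), plus a hand-rolled 1-D
SOM (a chain of k nodes initialized along the first principal axis, trained
with a shrinking Gaussian neighborhood; node = cluster). Per setting, every
k in [2, k_max] is fitted and each index nominates its k — Calinski–Harabasz
and silhouette by maximum, Davies–Bouldin by minimum, gap by the
one-standard-error rule (uniform bounding-box null, 20 references by
default) — and the silhouette choice is the setting's k.

Quality: Hopkins statistic (10% sample, uniform hyper-rectangle null;
~0.5 for spatial randomness, → 1 for clustered data), Dunn index (minimum
inter-cluster point distance over maximum intra-cluster diameter; singleton
diameter 0, all-singleton solutions map to infinity), and a Jaccard
bootstrap (B = 100 resamples, refit, greedy best-match Jaccard per original
cluster, averaged). `select_best` ranks candidates lexicographically on
(Jaccard, Hopkins, Dunn) rounded to 2 decimals — an explicit, configurable
convention, since "best" is otherwise under-determined — with first-wins
tie-breaking in input order.

Characterization tests each cluster against the rest: Welch t for continuous
covariates, χ² for sex (with an M:F ratio column), Fisher's exact for every
comorbidity tag regardless of expected counts, BH correction across the
whole table; arm incidence is reported without a test. Differential proteins
require both |cluster mean − overall mean| > 0.1 and Wilcoxon rank-sum
BH q < 1e-4. Classifier proteins use a single-feature threshold classifier
(threshold and direction chosen on the training folds by balanced accuracy)
under stratified 10-fold CV, folds reduced with a warning when a cluster is
small; pairs with BACC > 0.8 get a label-permutation p-value (the
"cross-validated p" is a permutation stand-in, the original procedure being
unstated).

## Enrichment

One-sided hypergeometric tail P(X ≥ overlap), computed exactly. Sets are
intersected with the protein universe first and kept only at intersected
size 10–300; BH runs across the tested sets and results are reported at
q < 0.01. The set linkage is the Dubuisson–Jain modified Hausdorff (max of
the two directed mean-of-minima) over shortest-path lengths in a supplied
protein-interaction edge list; the classical max-min Hausdorff is available
as a dialect. Disconnected node pairs default to (largest finite shortest
path + 1), configurable. Networks export to SIF ("setA link setB") and
GraphML with a node-attribute table; the GraphML round-trips exactly. Tests
use small synthetic graphs; no proprietary network is shipped.

## Sample-size estimation

Progressive sampling: for subset sizes from 10 upward, repeated stratified
subsamples are scored by the 10-fold cross-validated accuracy of the best
two-feature linear discriminant (exhaustive pair search up to 200 features,
greedy beyond). The minimum n for a threshold (e.g. 90%/95% of the
full-sample "max accuracy") is the smallest size meeting the threshold in at
least a stated fraction of repeats — "power" is read as that repeat
fraction, the original computation being unstated.

## Orchestration and reproducibility

The trial runner executes population → PBPK (both arms on the same
patients) → activities → tSignal → clustering → characterization → screens →
optional enrichment, and writes a manifest with record counts, a sha256 per
output file and per-stage seeds split deterministically from the global seed
via `SeedSequence.spawn` (so one stage's consumption never reshuffles
another's). Same config + seed reproduces the bundle byte for byte. Any
stage failure aborts with the stage name and offending record.

Problem sizes used by the test suite and acceptance script: populations of
20–500 patients, 30–124 proteins, 12-drug calibration panels, 60-patient ×
2-arm clustering scenarios, 100-instance exhaustive enrichment checks.

## Known limitations

- No target-mediated disposition, anti-drug antibodies, tissue penetration
  or placental transfer in the PK model; bioavailability and the
  distribution-volume adjustment are unvalidated configuration defaults.
- Comorbidities are independent; no co-occurrence structure, smoking or
  alcohol covariates, and no pediatric populations.
- The activity generator is a synthetic stand-in: quantitative agreement
  with published severity-marker correlations or clustering indices is out
  of reach by construction and not claimed.
- The weight/BMI marginal inconsistency bounds the population size at which
  the acceptance loop can satisfy its 0.5 SE window (ample at n = 500).
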