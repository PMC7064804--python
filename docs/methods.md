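# Methods

This package implements a resting-state fNIRS connectome analysis as a
tested, reusable pipeline: multichannel hemoglobin time series are
denoised, turned into per-subject functional-connectivity matrices,
thresholded into binary networks whose efficiency is summarized, and
compared between a patient and a control group with permutation-based
familywise-error control, followed by covariate-adjusted correlations
between connectivity features and symptom scores. Because clinical
recordings of this kind are not publicly deposited, the package ships a
synthetic-cohort generator with known ground truth; every statistical
stage is validated against that ground truth.

## Signal model and preprocessing

A recording is a channels × samples matrix of hemoglobin concentration
changes (µM) at sampling rate `fs` (default 17 Hz, 80 channels, 8-minute
usable segments). When raw optical intensities are the starting point,
the modified Beer–Lambert law converts optical-density changes at two
wavelengths into HbO/HbR concentration changes by solving the 2×2
extinction system per sample; the extinction table, interoptode distance
(3 cm) and differential pathlength factors (default 6.0) are editable
because vendor calibration tables differ. HbO is the default analysis
species (better signal-to-noise); HbR is supported behind a flag.

Preprocessing order is fixed: **bandpass → stable segment → temporal
ICA**.

- *Bandpass*: 3rd-order Butterworth, 0.01–0.1 Hz, applied
  forward–backward (zero phase) so that cross-channel correlations are
  phase-faithful; channel means are removed. Measured on a 600 s
  sinusoid, the realized filter passes 0.05 Hz within 1 % and attenuates
  1.2 Hz (cardiac) by more than 99.9 %.
- *Stable segment*: the contiguous window (default 480 s) minimizing the
  channel-mean variance of the first-differenced signal; earliest window
  wins ties.
- *Temporal ICA*: each channel is modeled as a mixture of K independent
  temporal sources (FastICA; K defaults to the principal components
  explaining 99 % of variance, capped at 30). Components are
  canonicalized — largest-|weight| channel positive, ordered by
  explained variance — so the decomposition is a pure function of the
  seed. Convergence failures are surfaced on the returned object, never
  hidden.

### Noise-component screening

Three algorithmic criteria replace the visual inspection usually used to
reject artifact components; a component is noise if **any** criterion
fires, and each flag records which:

1. **Temporal profile** — excess kurtosis > κ or maximum absolute first
   difference > m robust SDs of the first differences (robust SD =
   1.4826·MAD). Catches sudden jumps and spike bursts.
2. **Power spectrum** — dominant Welch frequency outside 0.01–0.1 Hz,
   with one spectral bin of tolerance for discretization (the zero bin
   is skipped).
3. **Spatial map** — fraction of channels loading above half the maximum
   |weight| exceeds φ; catches globally dispersive superficial
   physiology.

Defaults κ = 25, m = 20, φ = 0.6 were calibrated on the synthetic suite
by measuring both populations: FastICA estimates of genuine band-limited
hemodynamic components reach excess kurtosis ≈ 19 and diff-ratios ≈ 15
(FastICA maximizes non-Gaussianity, so both statistics are inflated on
strongly autocorrelated sources with few effective samples), while
injected spike artifacts sit at diff-ratios above 300 and drift/cardiac
components fall far outside the band. With these thresholds the
classifier flags all injected drift, cardiac, motion-spike and global
components across 50 seeded component sets with zero false flags.

*Known limitation*: a global superficial component that is itself
Gaussian and confined to the analysis band is statistically
indistinguishable from neural signal by temporal ICA (two Gaussian
sources are not separable), so its removal cannot be guaranteed; what
the ICA stage demonstrably removes is spike-like motion artifact and
out-of-band or globally dispersive structure that survives the filter.
The pipeline-level guarantee tested is that the full chain (filter +
ICA cleanup) moves the signal closer to the noise-free truth than the
contaminated input in ≥ 95 % of seeded runs.

## Connectivity and networks

Per subject, Pearson correlations between every channel pair give an
N×N matrix `r`; Fisher's transform `z = atanh r` variance-stabilizes it
(|r| is clamped to 1−10⁻¹⁵ so z stays finite; the diagonal is
undefined). Group statistics run on z values; each subject's binary
network comes from their own matrix.

Binarization keeps the `round(S·N(N−1)/2)` most strongly **positive** z
values as edges at sparsity S (default 0.2 → exactly 632 edges on 80
channels). Ranking on signed z reflects that the analysis concerns
positive resting-state coupling, so negative correlations fall to the
bottom; an |z| mode is available by flag. Ties break lexicographically
on the (i, j) pair, making the network deterministic and invariant to
positive rescaling.

## Efficiency metrics

On a binary undirected graph with hop distances d_ij (breadth-first
search; 1/∞ := 0 for disconnected pairs):

- global efficiency E_glob = (1/(N(N−1))) Σ_{i≠j} 1/d_ij,
- nodal efficiency E_nod(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij,
- local efficiency E_loc = (1/N) Σ_i E_glob(G_i), where G_i is the
  subgraph induced on i's neighbors (i excluded); nodes with fewer than
  two neighbors contribute 0.

The printed summation range of the nodal-efficiency formula in the
source literature reuses the global index set; the implementation
follows the harmonic-mean-over-all-other-nodes reading (the standard
definition), which makes mean(E_nod) = E_glob an exact identity — used
as an internal cross-check. All three are verified exactly against an
independent Floyd–Warshall + direct-summation oracle on 200 random
graphs, and against closed forms (E_glob(K_N) = 1, E_glob(P₃) = 5/6,
E_nod(K₁,₃ leaf) = 2/3, E_loc(K₃) = 1, E_loc(K₄ − e) = 11/12).

## Group inference

Edgewise two-sample t-tests (pooled variance by default, Welch by flag)
on Fisher-z values flag suprathreshold edges at two-tailed p < 0.001.
The network-based statistic groups suprathreshold edges into
node-connected components and refers each component's size (edge count)
to the permutation null of the **maximum** component size under random
group-label exchange (default 1000 permutations), with familywise
p = (1 + b)/(1 + P) so p can never be zero. Two-tailed edge selection
makes both decreases and increases eligible; each component's dominant
sign is reported. Pooled-variance t is the default because the published
demographic worked example (age row: t = 0.28 at n = 30/30) reproduces
under pooled variance.

Edges are classified **homotopic** (a declared contralateral homolog
pair), **intrahemispheric** (same hemisphere), or **heterotopic**
(across hemispheres, non-homologous). Midline channels have no homolog
and never cross hemispheres, so midline-touching edges are classed
intrahemispheric; the three classes partition every edge.

Symptom correlations residualize **both** the connectivity features and
the clinical scores on age, sex and education (OLS) before Pearson
correlation — numerically identical in r to partial correlation
controlling the same covariates (verified against an independent
implementation). p-values are two-tailed and uncorrected at α = 0.05,
matching the uncorrected exploratory convention; a Benjamini–Hochberg
option exists for the nodal group tests. A single-sex cohort makes the
sex indicator collinear with the intercept, so constant covariate
columns are dropped rather than failing.

## Synthetic cohorts

The generator is the ground truth against which everything above is
validated. Defaults mirror the acquisition being emulated: 80 channels,
17 Hz, 480 s, 30 subjects per group.

- *Targets*: block-structured correlation by functional-network label
  (within-network r = 0.35, between r = 0.10, homotopic boost +0.30),
  repaired to the nearest positive-definite correlation matrix by
  eigenvalue clipping and renormalization whenever edits break positive
  definiteness.
- *Planted effect*: a 6-edge clique on four same-network channels
  attenuated by δ = 0.25 in the patient group. Each subject carries one
  shared severity deviation (SD 0.10) across the planted clique — a
  single per-subject connectivity-deficit factor, which is what the
  symptom model couples to — plus small independent jitter (SD 0.03) on
  all edges for realistic between-subject variance.
- *Signal*: Gaussian noise colored to 0.01–0.08 Hz and mixed through the
  Cholesky factor of the subject's target correlation, giving exact
  control of target FC.
- *Nuisance terms*: linear drift, Mayer-band oscillation (0.1 Hz),
  cardiac sinusoid (1.2 Hz), a shared band-limited superficial
  component, and motion spikes — exponentially decaying jumps at
  Poisson-timed events shared across channels (head motion moves every
  optode at once) with channel-specific amplitude and sign.
- *Scores*: inattentive and hyperactive/impulsive scores are linear in
  the subject's realized planted-edge strength (weights −6 and −10:
  weaker connectivity, worse symptoms) plus covariate terms and Gaussian
  noise (SD 1), clipped at zero; total is their sum. Group intercepts
  put the group means near the published clinical summaries, though the
  generator's score SDs are intentionally smaller than clinical ones so
  that coupling recovery is testable at n = 30. Study cohorts are
  boys-only by default (`male_fraction = 1.0`); lower it to exercise the
  sex covariate.

Everything is a pure function of (config, seed); per-subject streams are
derived through `SeedSequence` so cohorts are reproducible bit for bit.

What the generator does **not** emulate: physics-based photon
transport, coupled HbO/HbR hemodynamics (HbR is a scaled anti-correlated
copy), non-Gaussian neural dynamics, spatially smooth artifact
topographies, or clinical comorbidity structure. Passing recovery tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not clinical validity on real recordings.

## Validation conditions and problem sizes

The statistical suites run at the design conditions: familywise error of
the NBS is estimated from 100 null runs (40 channels, 30 + 30 subjects,
1000 permutations each) and must stay within the upper 95 % binomial
band around 0.05; planted-clique recovery uses 50 runs at 80 channels
(a significant component containing ≥ 4 of the 6 planted edges in
≥ 90 % of runs); symptom-coupling recovery uses 200 patient cohorts
(significant negative partial correlation in ≥ 95 %). Null and recovery
cohorts are generated with nuisance amplitudes zeroed to isolate the
inference stage; the preprocessing chain is validated separately (50
seeded runs at 40 channels, 300 s). The demo pipeline configuration (20
channels, 10 per group, 5-minute recordings) exercises every stage in
seconds and is the default for the command-line interface.

## Numerical choices

- Correlations are clamped to |r| ≤ 1−10⁻¹⁵ before `atanh`.
- Efficiency convention 1/∞ := 0 handles graphs disconnected at S = 0.2.
- Positive-definiteness repair floors eigenvalues at 10⁻⁴ and
  renormalizes the diagonal; a tiny ridge (10⁻¹⁰) guards the Cholesky.
- Matrices and recordings are written with `%.17g`, so write→load is the
  identity on IEEE-754 doubles and reruns are byte-identical.
- The permutation p estimator (1 + b)/(1 + P) bounds p away from zero at
  1/(P+1).
- `residualize` rejects genuinely collinear covariates (design condition
  number > 10⁸) but silently drops constant columns (single-sex
  cohorts).
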