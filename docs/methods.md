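# Methods

## Infant haemodynamic response function

Term-infant BOLD responses peak later than the adult canonical response and
show a pronounced late undershoot. The canonical kernel here is a
double-gamma function

```
h(t) = g1(t; a1, b1) − c · g2(t; a2, b2),      a1 = 6, a2 = 16
```

with both lobes peak-normalised gamma densities. Only two observable
constraints define the kernel — time-to-peak 7 s and undershoot-to-peak
ratio |min h| / max h = 0.49 — and these identify exactly two free
parameters. The positive-lobe scale `b1` and undershoot amplitude `c` are
solved by alternating bisections (the undershoot mode is tied to twice the
peak time, the conventional spacing; it is not identified by the two
constraints, so it is not searched). The scale is solved last so the
sampled argmax lands exactly on the target sample; calibration failure
raises with the residuals. `calibrate_infant_hrf` is deterministic and runs
in well under a second at dt = 0.01 s.

The three-function basis is the canonical kernel plus its temporal
derivative (finite differences) and a dispersion derivative (numerical
sensitivity to a 5% stretch of the time axis), both orthogonalised against
the canonical and peak-normalised. The true second and third functions of
the infant-optimised basis are not published in closed form; the
derivative surrogate is the standard choice and is flagged as a surrogate,
not asserted as equivalent. Only the canonical coefficient enters
downstream quantification, so the surrogate choice does not move the
headline numbers.

## Design matrices

Stimuli are laid down as unit impulses on the basis's fine grid (dt =
0.1 s by default; the ~1 s stimulus duration is small relative to the HRF
width and is recorded but not convolved as a boxcar), convolved with each
basis function, and sampled at volume acquisition times `i·TR`. This
sampling convention matches the `floor(t/TR)` stimulus-to-volume assignment
used by the window extractor, and makes an impulse at t = 0 with dt = TR
reproduce the basis at volume times exactly. TR must be an integer
multiple of the basis dt. Motion-outlier volumes add one unit indicator
column each.

## ROI extraction and preprocessing

Masks are binary or weighted (weighted for small brainstem nuclei such as
the RVM); extraction is the per-volume weighted mean with weights
normalised to sum 1. Two exclusion rules precede extraction:

* **Signal dropout** — voxels whose temporal-mean intensity falls more than
  10% below a maximum-signal reference are removed. The reference is the
  98th percentile (configurable) of the mean image over the mask union
  rather than the literal maximum, which is a single noisy voxel. An ROI
  losing all voxels raises an error naming the region.
* **CSF** — voxels labelled CSF in an aligned segmentation are removed; a
  segmentation with no CSF label anywhere warns and leaves the mask intact.

High-pass filtering at 0.01 Hz uses Gaussian-weighted running-line
detrending (local linear fit under Gaussian weights of width
σ = period/2), the convention of the FSL toolchain the analysis mirrors,
implemented as a cached linear operator. A cutoff at or above Nyquist is
rejected. Demeaning is applied to the full-length series before window
extraction, not per window. Grand-mean scaling is available but off by
default for pre-extracted series, since whether it preceded extraction in
the original toolchain is not stated.

## Pre-stimulus connectivity

Per-stimulus 3-point Pearson correlations are averaged arithmetically
(a Fisher-z option exists but is off by default, following the method's
plain-average definition). A zero-variance 3-point segment makes that
stimulus's correlation undefined; it is dropped from the average with a
logged count rather than set to 0, so undefined values cannot bias toward
the null. Network psFC is the mean of the below-diagonal entries of the
connectivity matrix restricted to the network, and the same machinery
serves the brainstem-excluded subsets and the per-stimulus (stability)
decomposition. Averaging order is exactly interchangeable: the mean over
stimuli of per-stimulus network means equals the network mean of the
averaged matrix.

## Evoked response

DVARS is the RMS over ROIs (or voxels) of the volume-to-volume difference;
volumes above the boxplot upper fence (Q3 + 1.5·IQR, or a configurable
absolute threshold) are flagged. The GLM is ordinary least squares with an
internal intercept; the data and the task regressors pass through the same
high-pass operator. Percent BOLD change follows the Featquery-style
convention `100 · β_canonical · regressor_peak / mean_raw_signal`,
averaged over the activity-mask units; the convention string is recorded in
the output so alternative conventions remain comparable. The group-level
mixed-effects cluster analysis that produced the original activity mask is
not re-implemented — the mask is an input, and for synthetic data it is the
set of ROIs the generator marks as responsive.

## Association statistics

The age-adjusted correlation residualises the *response* on GA (intercept
included) and correlates the residuals with psFC, matching the description
of the source analysis; the symmetric partial-correlation convention is
available behind `partial=True` and the two agree exactly whenever psFC is
orthogonal to GA in-sample. Edgewise models report unadjusted p-values
(no correction was described for the original per-edge screen); a
Bonferroni column is added for transparency but does not drive the
significance flags. The repeated-measures ANOVA is the classical univariate
F with subject as the blocking factor, computed from explicit sums of
squares so the within-subject error MS is available for Tukey HSD via the
studentized-range distribution on the RM error term — a combination the
installed statistics packages do not expose directly; `pingouin.rm_anova`
cross-checks F and p in the test suite. Degenerate tables (no condition
effect and no error) return F = 0, p = 1; sphericity corrections are not
applied by default since the original analysis does not mention them. GA
is handled in decimal weeks (weeks + days/7).

## Synthetic cohorts

Each infant is generated as, per ROI,

```
baseline · U(0.9, 1.1) + drift + strength · loading · f_net(t) + evoked + noise
```

where `f_net` is a unit-variance mixture of six sinusoids confined to
0.01–0.08 Hz (band-limited by construction, so slow shared fluctuations
survive the high-pass filter and carry the 3-point window correlations),
`loading ~ U(0.8, 1.2)`, and noise is white Gaussian. A latent DPMS
coupling `γ` scales the DPMS factor's strength and sets the evoked
amplitude `A = intercept + slope·γ + ε` (percent of the ROI's own
baseline); Control and DMN strengths are drawn independently of `γ`, with
the DMN given a 1.5× factor to mirror its higher resting coherence. The
evoked train is built through the same design-matrix path used for fitting,
so noise-free sessions are exactly recoverable. GA ~ U(38, 43) weeks is
independent of `γ` by default, with a Gaussian-copula switch to induce
GA–coupling correlation for covariate-adjustment tests. All latents are
serialised per infant; a fixed seed reproduces cohorts bit for bit.

Default noise levels (`noise_sd` 5, `shared_fluct_sd` 6, drift 5 on a
baseline of 1000) were chosen so that the measured network psFC means sit
near the observed infant values (≈ 0.09 / 0.15 / 0.22 for DPMS / Control /
DMN); the true variance decomposition of infant BOLD is unknown, and these
levels are a structural emulation, not a claim about the study data.

Three named conditions freeze the simulation studies:

* `strong_coupling_config` — the recovery regime, calibrated by simulation
  sweep so the pooled age-adjusted r between measured psFC and measured
  percent change is ≈ −0.85. Ten 3-point windows put an irreducible
  sampling-noise floor under measured psFC: the pooled r plateaus near
  −0.84 regardless of how small the other noise sources are made, and
  reaching that floor requires stronger shared fluctuations (hence higher
  psFC levels) than the default structural emulation. At n = 13 the
  estimated r is negative in ≥ 95% of cohorts.
* `null_coupling_config` — slope 0; the psFC term's rejection rate is
  nominal (≈ 5% at α = 0.05 over 1000 cohorts, p-values uniform).
* `targeted_edge_config` — a single pair (default ACC–PAG) carries the
  coupling through its own latent factor. Two structural facts shape this
  condition. First, with the activity mask on DPMS ROIs, evoked-response
  tails (HRF support 32 s vs ISI ≥ 25 s) leak into the next stimulus's
  pre-window and couple active-ROI pairs in proportion to the evoked
  amplitude, which can hand other edges the largest |β|; the activity mask
  is therefore placed on non-DPMS ROIs here. Second, edges touching the
  loaded nodes are *diluted* as the pair factor grows (variance dilution),
  an effect the tests assert rather than hide. With 40 infants the loaded
  edge tops the |β| ranking in ≈ 98% of cohorts.

What the generator does **not** emulate: scanner physics, realistic motion
(beyond global spike volumes), cardiac/respiratory waveforms, spatial
autocorrelation within ROIs, and any empirical infant variance
decomposition. Passing recovery tests therefore demonstrates correctness
of the estimator chain under the stated generative model, not robustness
to every artefact of real infant data.

## Problem sizes

Simulation studies run at: 500 cohorts (recovery), 1000 cohorts (type-I),
100 random fixtures (oracle equivalence), 25–40 cohorts for the targeted
and sensitivity conditions — sizes at which every Monte-Carlo bound in the
test suite is stable across seeds on a single CPU.

## Known limitations

* The pre-stimulus window may contain the tail of the previous trial's
  response (ISI ≥ 25 s < HRF support); no additional exclusion is applied,
  matching the source method, and the leakage consequence is documented
  above.
* The undershoot delay of the canonical kernel is a convention (2× peak
  time), not an estimate.
* The dropout-reference percentile (98th) is a robustness choice; the
  literal per-image maximum is supported via configuration.
* Volume-rendering fixtures place ROIs as disjoint cubes on a small grid —
  a geometry for exercising mask arithmetic, not anatomy.
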