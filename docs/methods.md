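# Methods

This note documents the models, parameter choices and numerical decisions
behind `reachnet`, and what the synthetic-data validation does and does not
demonstrate about real EEG.

## Analysis model

### Epoch and window conventions

Epochs run from −1 to +3 s around the cue at 512 Hz, as half-open sample
ranges `[tmin, tmax)`, so every trial has exactly 2048 samples and the cue
sits at sample 512. All windows are half-open: baseline `[−1, 0)`, early
post-cue `[0, 1)` (never analysed — dominated by the visual evoked
response), late post-cue `[1, 2)` (movement preparation), movement from
2 s. Frequency bands are half-open too — alpha `[8, 13)` Hz, beta
`[13, 30]` Hz with a closed upper edge — so the shared 13 Hz boundary is
counted once. Note the classical scale description of these bands (scales
64…42 and 42…16 at 512 Hz) does not exactly match the Hz edges (scale 42 ↔
12.19 Hz, 16 ↔ 32 Hz); this package follows the band definitions in Hz.

### ERSP

Time–frequency power comes from the continuous wavelet transform with the
complex Morlet `cmor1.5-1.0` wavelet. The transform reuses PyWavelets'
integrated-wavelet filters but runs the convolution as a batched FFT with
one shared padded length across scales; it is tested for equality against
`pywt.cwt` to < 1e−10. The default analysis grid is 1 Hz-spaced center
frequencies from 4 to 32 Hz.

Per-trial power is averaged per reaching target, then normalized per
frequency to percent change from the mean baseline power
(`ERSP = 100·(P−B)/B`); per-target maps are averaged across targets only
after the across-target cluster tests, mirroring a test-then-pool design.
By construction the baseline-window mean of an unmasked ERSP map is exactly
0 at every frequency.

**Baseline validity masking.** Two biases contaminate a naive baseline mean,
both consequences of the wavelet's Gaussian support (std = scale·√(bw/2)
samples): (i) near the epoch edge the implicit zero padding biases power
low, inflating all ERSP values (≈ +2.5 percentage points at band level);
(ii) the cue-evoked transient smears *backwards* into late-baseline
samples, biasing evoked-ROI ERSP down by ≈ −1 pp. Both are invisible in a
single map but become systematic cohort-level effects that a 20-subject
Wilcoxon battery happily "detects". The pipeline therefore excludes
baseline samples within 4σ of an epoch edge and within 3σ before a stimulus
onset from the *baseline mean only* (`ersp_coi_baseline=True`; the maps
themselves are never masked, and `compute_ersp`'s default remains the plain
window for anyone wanting the textbook definition). If a frequency's valid
set is empty the mask falls back to the edge rule, then to the plain
window — relevant only below ≈ 6 Hz, outside the analysed bands.

**Decimation.** The ERSP arm decimates 512 → 128 Hz (zero-phase FIR) before
the transform; every analysed frequency is ≤ 32 Hz, a quarter of the
decimated Nyquist, and the saved factor ≈ 16 in transform cost makes
cohort-scale runs interactive. `ersp_decimate=1` disables it.

### Spectral Granger causality

The evoked potential is removed per reaching target (different targets may
evoke different responses) before windowing. Windows are demeaned per trial
and ROI; the bivariate VAR (p = 30) is fitted by OLS on lagged design rows
accumulated within each 1-s segment only, so no regression row mixes
trials. No intercept is fitted. The residual covariance uses the
maximum-likelihood 1/n scaling — at ≈ 29 000 rows per fit the distinction
from 1/(n−2p) is far below every tolerance used here. The normal matrix is
assembled once per condition from per-ROI lag Gram blocks, making the
120-unordered-pair battery a sequence of 60×60 solves; its condition number
is checked against 1e10.

The GC spectrum is evaluated on a 0.5 Hz grid from 1 to 45 Hz. The ratio
inside the log is invariant to the one- vs two-sided spectral convention,
so the internal two-sided convention is immaterial. Denominators are
floored at `1e−12·S_ii` and tiny negative values clamped to zero; clamp
events are counted and reported in the run manifest. Fitted systems whose
companion radius reaches 1 produce a warning and are flagged, not fatal.

Only pairwise (bivariate) GC is implemented — no conditional/multivariate
variants, no nonparametric spectral factorization, no time-varying GC.

`synthetic.analytic_spectral_gc` evaluates the same Geweke decomposition in
closed form on the *true* coefficients, in a deliberately separate,
loop-based code path, so estimator and oracle can cross-check each other
(they agree to < 1e−10 when the estimator is handed the true parameters).

### Degrees and statistics

In/out degrees are column/row sums of a GC matrix. For a normalized matrix
both degree vectors sum to exactly 1 (conservation).

* **Wilcoxon signed-rank** — zero differences dropped; exact null by
  subset-sum enumeration (ties included, via doubled midranks) for ≤ 15
  non-zero differences; otherwise normal approximation with tie correction
  and a 0.5 continuity correction. Empirical type-I error at α = 0.05 is
  verified by simulation in both modes.
* **BH-FDR** — statsmodels' step-up implementation behind a thin surface;
  cross-checked against a hand-worked example and monotonicity properties.
* **Paired permutation** — statistic = mean paired difference, null by
  independent subject-level sign flips, `p = (1+#{|perm|≥|obs|})/(n_perm+1)`
  with 5000 permutations. Batteries (the 240 ordered pairs) share one
  sign-flip matrix: exchangeability is a property of subjects, not of
  tests, and sharing keeps the battery inside one matrix product.
* **Cluster permutation (1-D)** — point-wise paired t, threshold at the
  two-sided 0.05 critical value (configurable), cluster mass = summed t,
  null = max |mass| under sign flips. Only `Σd²` is needed per permutation
  (it is sign-flip invariant), so the permuted t series is a single matrix
  product.

**Which matrices feed the contrasts.** Band-averaged GC matrices exist raw
and normalized (off-diagonal sum 1). The per-connection permutation battery
and the degree battery default to the **raw** matrices; the normalized ones
are computed, written, and used for the relative-contribution maps. Reason,
demonstrable on ground truth: per-condition normalization is a closure
operation — one genuine local increase (or the ERD-driven inflow inflation
described below) mechanically depresses every other normalized entry by a
small, cohort-consistent amount, which the paired tests then flag en masse
(10–25 % false-positive rates in our cohorts). Both choices are exposed
(`gc_contrast_on`, `degree_contrast_on`).

**A genuine property worth knowing.** GC is a ratio: if an ROI's band power
drops (ERD) while the causal power flowing into it is unchanged, its
measured inflow GC *rises* — `GC_{j→i} ≈ causal/S_ii` for small values. An
amplitude ERD therefore produces a real increase of the ERD ROI's
in-degree, distributed across all sources (and hence a small rise of every
ROI's out-degree). This is not an estimator bug; it is what band-limited GC
measures. The planted-recovery tests account for it by treating the ERD
ROI as an affected node, and the degree-specificity claim is made on a
coupling-only cohort.

## The synthetic cohort

Defaults emulate the study conditions: 20 subjects, 5 targets, 60
trials/target (300 trials), 16 ROIs labelled `L./R. CU, LO, PCU, SP, PoC,
PrC, PaC, SF`, epochs −1 to 3 s at 512 Hz.

Each trial sums:

1. **VAR background** (innovation std 0.25): self terms (0.5, −0.2) at lags
   1–2 plus a feed-forward web — posterior→anterior chains within each
   hemisphere (lag 1, weight 0.12) and left→right homologous links (lag 2,
   weight 0.08). The post-cue system adds one directed edge
   L.SP → L.PrC (lag 1, weight 0.1), the planted connectivity change.
   Coefficients cross-fade over 50 ms starting 0.5 s post-cue (the
   generative switch time is not an analysis parameter; both analysis
   windows see a stationary system). The feed-forward topology keeps the
   planted change's downstream set well defined.
2. **Oscillations**: 10 Hz (amp 1.0) and 20 Hz (amp 0.6) amplitude-
   modulated sinusoids on every ROI with uniform random per-trial phase, so
   trial-averaged evoked contamination of induced power is negligible. ERD
   is programmed on L.PoC (alpha gain 0.5, beta gain 0.7) via a linear
   amplitude ramp from 0.5 to 1.0 s — fully expressed throughout [1, 2) s,
   where the induced perturbation equals 100·(g²−1) exactly. The
   oscillation-to-background power ratio inside a band is high (≈ 30), so
   the programmed gain dominates the measured band ERSP; this emulates
   strong idling rhythms.
3. **Evoked transient**: a damped 5 Hz burst (0.5 s, exponential decay 8/s,
   < 5 % of peak after 450 ms) on the visual/visuomotor ROIs, with 10 %
   per-trial amplitude jitter.
4. **1/f noise** (std 0.05) by spectral shaping of white noise.

Between-subject variability: log-normal jitter of the innovation scale
(10 %), of every oscillation amplitude (10 %, per ROI per band), and of
every coupling coefficient (15 %, identical in both systems so the
condition contrast stays the programmed one). Jittered systems are
re-checked for stability. All randomness descends from one master seed via
`SeedSequence` spawning (per subject, per stage); identical configuration
and seed reproduce every array bit-for-bit.

**What passing on this generator shows — and what it does not.** The
generator validates recovery of programmed spectral perturbations and
directed coupling under realistic trial counts, subject variability, evoked
contamination and 1/f noise. It does not contain volume conduction /
leadfield mixing (generation is at ROI level by design), non-Gaussian or
non-stationary artifacts, heteroscedastic trial noise, or inverse-solution
errors — so passing tests certify the analysis chain, not robustness of
source reconstruction upstream of it.

## Problem sizes used in the validation suite

Unit tests run on 2–3-node systems and reduced cohorts. The end-to-end
recovery and the coupling-only degree-specificity checks run the full
default study (20 subjects × 300 trials); estimator-consistency checks use
300 s of concatenated data; statistical calibration uses 1000–2000 null
replicates per test. The reference-number script generates one full-size
subject.

## Known limitations

* Pairwise bivariate GC inherits the usual caveats: common input and
  cascades (A→B→C) can produce nonzero pairwise GC where the conditional
  quantity would vanish, and a strong source amplitude change shifts
  estimated GC for pairs involving that source. The planted-source ROI
  shows a genuine in-degree increase via such common-history effects.
* The exact Wilcoxon switches to the normal approximation above 15 non-zero
  differences; with 16–25 subjects the approximation (with tie and
  continuity corrections) is calibrated but p-values near discreteness
  boundaries differ slightly from full enumeration.
* Cluster-test inference is at cluster level only; cluster extent has no
  location-wise error guarantee.
* The ERSP edge/evoked baseline masking leaves frequencies below ≈ 6 Hz
  with partially contaminated baselines in a −1 s epoch (their valid
  baseline set can be empty); the analysed bands are unaffected.
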