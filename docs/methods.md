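# Methods

This note documents the models, numerical choices and limitations behind
`alphalat`. Everything quantitative stated here is computed by the test
suite or the acceptance script; nothing is asserted from memory.

## Paradigm and containers

Each trial of the emulated experiment is a sequence of auditory events:
pre-cue (400 ms) → 1,000 ms ISI → three-sound array (600 ms) → 1,000 ms
delay → retro-cue (400 ms) → 1,000 ms → probe. All epoch times are stored
in ms relative to **pre-cue onset**; the retro-cue onset is therefore the
derived constant 3,000 ms, and windows specified "post retro-cue" are
shifted by +3,000 ms internally.

Epochs span −1,000 to 7,500 ms at 500 Hz (4,250 samples). The native
container is a flat little-endian float32 array plus a JSON sidecar;
channels are canonicalized alphabetically on write and addressed by 10/20
label only. Trial tables are CSV with validated categorical columns; the
design constraint that a neutral retro-cue cannot be followed by a
non-cued probe is enforced at every read.

## Trial design generator

Four retro-cue types appear at exactly 25% each: target-lateral left
("li"), target-lateral right ("re"), distractor-lateral ("mi"), neutral
("bei") — so 50% of trials are target-lateral. Probes are 50% cued (YES),
25% non-cued, 25% new (NO), with neutral trials drawing only cued/new.
`n_trials` must be divisible by 16; all the proportions above are then
exact at the pool level. Within the three selective cue types the
non-cued/new remainders cannot always divide evenly (that would require
divisibility by 48), so they are distributed near-evenly in a fixed token
order — a deterministic choice, documented here because per-type probe
composition is not otherwise pinned down. Trials are arranged in blocks of
100 and shuffled pseudo-randomly from the seed.

## EEG simulator

Every channel carries 1/f pink noise (exponent 1, RMS 10 µV), synthesized
spectrally with exact expected RMS. The eight posterior cluster channels
additionally carry a 10 Hz oscillation (amplitude 6 µV, random phase per
trial and channel). Inside the effect window (700–1,300 ms post retro-cue,
100 ms raised-cosine ramps) the two hemispheres' amplitudes are set so
that the **expected** ALI at the alpha frequency equals the condition's
injected value (+0.2 target-lateral, −0.2 distractor-lateral, 0 neutral by
default, with optional between-subject SD 0.08).

The calibration inverts the ALI ratio including the noise floor: with
wavelet gain *k* (squared sinusoid amplitude → wavelet power, computed
from the analysis wavelet's transfer function) and noise floor *N* (exact
bin sum of the pink-noise synthesis variance through the wavelet), total
baseline power is P₀ = N + k·a₀², and the hemispheric amplitudes solve
ipsi = P₀(1+ALI), contra = P₀(1−ALI). Targets outside the feasible range
(which would need negative power) raise an error.

Two consequences worth knowing:

- the injected ALI is exact *at the alpha centre frequency*; window means
  over the full 8–13 Hz × 600 ms window are attenuated (roughly 0.13–0.17
  recovered for ±0.2 injected at the default settings) because off-peak
  frequencies are noise-dominated. Sign-level and detection claims are
  unaffected, which is what the tests assert.
- the simulator produces a single coherent sinusoid per channel rather
  than bursty, bandwidth-limited alpha; real data have broader spectral
  structure, ocular artifacts, and ERPs to the probe, none of which are
  emulated. Passing tests therefore validate the analysis machinery, not
  claims about real-data effect sizes.

## Behavioral simulator

RTs are log-normal (trial-level σ = 0.25 log units) parametrized by their
mean: neutral-cue mean 900 ms, selective cues faster by `rt_benefit_ms`
(default 60), non-cued probes slower by `interference_ms` (default 80).
Subjects get a random intercept (SD 50 ms) and random effect deviations
(SD 25 ms). Errors are Bernoulli on an error-rate scale (base accuracy
0.92, non-cued error rate doubled, log-normal subject multiplier), which
makes `accuracy_base = 1` yield literally perfect performance. A 2% lapse
rate produces premature (< 200 ms), late (> 2,100 ms = 1,500 ms after
probe offset) and missing responses in equal shares; all count as errors.
The study reports only test statistics for behavior, so these effect sizes
are free simulation parameters, chosen once as plausible values.

## Preprocessing

- **Channel rejection**: excess kurtosis per channel over the concatenated
  signal, z-scored against the 20%-trimmed mean and trimmed SD of the
  across-channel kurtosis distribution (trim split 10% per tail); channels
  with z > 5 are removed, except a protected list (anterior lateral sites
  in the original montage). Trimming makes the reference robust against
  the very outliers being detected.
- **Average reference** subtracts the across-channel mean per sample.
- **Trial rejection**: iterative; a trial is flagged when any
  channel-sample value exceeds 5 SDs of the across-trial distribution at
  that channel-sample or 1,000 µV absolutely; at most 5% of remaining
  trials (worst first) are removed per iteration until none are flagged.
  The statistic's granularity (per channel-sample) is a documented choice —
  the strictest natural reading of a bare "5 SD" criterion — and is
  configurable. The procedure is idempotent on its own output.
- **Downsampling**: FIR anti-alias + integer decimation only.

Band-pass filtering, ICA-based ocular correction, dipole screening and
channel interpolation are deliberately out of scope: synthetic epochs are
already band-limited, and real data are expected to arrive cleaned.

## Time–frequency decomposition

Complex Morlet wavelets on a geometric frequency grid: 52 steps from 4 to
30 Hz. Cycle counts interpolate **linearly in frequency** between 3 (at
4 Hz) and 11.25 (at 30 Hz); both endpoints are honored exactly, which is
the one rule consistent with both printed values (toolbox "expansion
factor" conventions are ambiguous, so the endpoints are treated as
authoritative). Wavelets are Gaussian-windowed complex exponentials with
σ_t = cycles/(2πf), truncated at ±3.5 σ_t and unit-energy normalized;
power is |convolution|², computed in the frequency domain with zero
padding (exact linear convolution), with no baseline correction — the ALI
is a ratio of raw power.

Time points within half the *widest* wavelet's support of the epoch edges
are discarded. At the defaults this retains −582 to 7,080 ms — the
retained span is derived, not hard-coded, and the ±3.5 σ truncation is
what makes the arithmetic land on those round values at 500 Hz. Power is
sampled at 200 evenly spaced points of the retained span (equal spacing
assumed; the grid is configurable).

## Lateralization index

Power is averaged over the four posterior electrode pairs per hemisphere,
with the left-hemisphere member ipsilateral when the lateralized item —
always the item on the pre-cued side: the target in target-lateral and
neutral trials, the distractor in distractor-lateral trials — is on the
left. Trial-mean ipsi and contra power are formed **before** the ratio
(averaging per-trial ALIs is not the same operation and is deliberately
not offered). ALI at zero total power is defined as 0, unreachable with a
pink-noise floor. Window means use closed intervals on the grid:
8–13 Hz × 3,700–4,300 ms epoch time.

## Cluster-based permutation test

Pointwise paired t (two-tailed, n−1 df; zero-variance points get t = 0,
p = 1 with no supra-threshold contribution) → supra-threshold points
(p < .05) → maximal 4-connected components (no diagonal adjacency — the
conservative common choice) of uniform t-sign (sign-mixed clusters are
physically incoherent; configurable in principle via the sign masks).
The null permutes condition labels within subject — an independent
swap/keep per subject, equivalent to sign-flipping difference maps, which
is the only label randomization that preserves the paired design. Each
iteration records the maximum cluster size (0 if none). The cutoff is the
empirical 95th percentile ("inverted CDF": smallest null value whose
cumulative fraction reaches the rank), and observed clusters must be
**strictly larger** to be significant.

The engine is vectorized: under sign-flips s the pointwise t is
m/√((q−m²)·n/(n−1)/n) with m = mean(sᵢdᵢ) and q = mean(dᵢ²) invariant, so
all permutations reduce to one sign-matrix × difference-map product. A
full-scale run (1,000 permutations, 20 subjects, 52×200 grid) takes a few
seconds on one CPU. Family-wise error control is verified empirically on
200 label-exchangeable null datasets (20×30 grid, 500 permutations): the
fraction of datasets with any significant cluster stays below
0.05 + 2·MC-SE (the measured value is conservative, partly because of the
strict inequality on a discrete size distribution).

## Statistics suite

- *t*-family: scipy tests; effect sizes Hedges *g* (paired: mean
  difference / SD of differences) and *g₁* (one-sample), both with the
  small-sample correction J = 1 − 3/(4·df − 1). The paired-*g*
  denominator has toolbox variants; the difference-SD convention is fixed
  here and stated.
- Wilcoxon signed-rank: exact null for n ≤ 25 without ties, otherwise the
  normal approximation with tie and continuity corrections (the
  continuity-corrected approximation agrees with exact enumeration to
  within 0.01 at n = 18, which the uncorrected version does not).
- Repeated-measures ANOVA (one-way) via pingouin: F with (k−1, (k−1)(n−1))
  df, partial η²; Mauchly's test gates Greenhouse–Geisser correction of
  both df (applied when Mauchly p < .05; ε ≡ 1 for k = 2). Flat
  between-level data short-circuits to F = 0 exactly.
- Friedman's ANOVA: rank χ² with k−1 df, mid-ranks for ties (scipy);
  constant data returns χ² = 0.
- Lilliefors normality gate (statsmodels, table-based p): parametric tests
  are used when p > .05 on the relevant difference scores, otherwise the
  rank-based alternative.
- FDR: Benjamini–Hochberg step-up within families, monotone, **not capped
  at 1**; a Benjamini–Yekutieli dependence-corrected variant is available
  under which adjusted values above 1 arise and are reported as-is.
  Families mirror the analyses: {cue-type, probe-type} per behavioral
  measure, post-hocs within their own family, and one family of five for
  the ALI follow-up (2 paired contrasts against neutral + 3 one-sample
  tests against zero).
- JZS Bayes factors: BF₁₀ for t-designs, Cauchy prior on the standardized
  effect (default scale √2/2), computed by adaptive quadrature of the
  noncentral-t likelihood against the prior; cross-checked in the tests
  against an independent quadrature of the equivalent variance-mixture
  form and against pingouin to 4 significant digits.

## Problem sizes used in validation

The full study (800 trials × 20 subjects) is more simulation than a test
suite should carry, so validation uses: 160 trials/subject for the
20-subject parameter-recovery cohort (full 52-frequency family, 200-point
grid, 1,000-permutation cluster test), 200 × 500-permutation null datasets
on a 20×30 grid for FWER, and 150 × 20-subject cohorts for behavioral
null calibration. These sizes are the package's validation choices; the
generator's defaults remain the study's (800 trials, 500 Hz, ±0.2
injected ALI).

## Known limitations

- The simulator's alpha is a stationary, narrowband sinusoid; no bursts,
  no 1/f-embedded bandwidth, no eye movements or probe-evoked responses.
- Only one-way repeated-measures designs are supported; no two-way ANOVA,
  no Bayesian ANOVA, no cluster-mass/TFCE statistics, no electrode-space
  clustering (power is averaged over the cluster before testing).
- EDF import is a thin optional path (requires `mne`) for continuous
  recordings plus an event table; proprietary vendor formats are out of
  scope.
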