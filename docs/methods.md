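# Methods

This document records the exact definitions, parameters and numerical choices
implemented in `somnomorph`, and what the synthetic generator does and does
not emulate.

## 1. Hypnogram metrics (`somnomorph.hypnogram`)

A hypnogram is a sequence of 30-s epochs labelled `W, N1, N2, SWS, REM`, with
an inclusive lights-out epoch and an exclusive lights-on epoch; epochs outside
that window are ignored by every metric.

| metric | definition |
|---|---|
| sleep onset | first N2 epoch at or after lights out (undefined → error) |
| SOL | (onset − lights out) × 0.5 min |
| TST | count of non-wake epochs in bed × 0.5 min |
| SPT | onset through the last non-wake epoch, inclusive |
| WASO | SPT − TST (literal identity; exact for every input) |
| sleep efficiency | 100 × TST / time in bed |
| awakenings | maximal contiguous wake runs strictly inside the SPT |
| stage % | stage epochs inside the SPT as % of SPT |
| event indices | events per hour of TST (arousal, PLMS, PLMS-arousal, AHI, apnea) |

Because TST counts *all* non-wake epochs in bed while the SPT starts at the
first N2 epoch, a night with sleep before onset (rare under an N2-defined
onset) can yield WASO < 0 under the literal identity; the identity is kept
rather than silently redefined. The eligibility screen fails a record iff
the PLMS-arousal index or the apnea index strictly exceeds 5.0/h (exactly
5.0/h passes).

## 2. Spectral engine (`somnomorph.spectral`)

Per 30-s epoch at 200 Hz (6000 samples):

- 512-point windows, 50% overlap → 22 windows per epoch, hop 256.
- Each window is demeaned and linearly detrended (least-squares line).
- Parabolic Welch taper `w[n] = 1 − ((n−(N−1)/2)/((N−1)/2))²`.
- One-sided power `|X_k|² / (N · Σw²)`, doubled for interior bins (the even
  window makes the Nyquist bin single); averaged over the 22 windows. With
  this normalization the summed linear power over all bins estimates the
  signal variance (white-noise check: ratio 0.996 at 500 epochs).
- Frequency grid: `k · 200/512` Hz, spacing 0.390625 Hz, 257 bins to 100 Hz.
- Band power: natural log of summed linear bin power over bins whose center
  lies in the half-open interval `[low, high)`. Half-open edges make the
  bands partition the axis without double counting (12.0 Hz belongs to
  sigma1, not alpha).
- Bands: delta1 0.1–1, delta2 1–3.5, theta 3.5–8, alpha 8–12, sigma1 12–14,
  sigma2 14–16, beta1 16–24, beta2 24–32, gamma 32–48, total 0.1–48, and a
  separate `total_screen` 0.8–48 used only by the artifact screen.
- A linear power floor of 1e-300 guards the log against exact zeros (an
  identically-zero epoch yields a finite, extremely negative log power rather
  than −inf).

Note that on the 0.390625-Hz grid, delta1 `[0.1, 1.0)` contains exactly bins
1 and 2 (0.39, 0.78 Hz); the 0-Hz bin is excluded everywhere.

## 3. Deviant-epoch screen (`somnomorph.artifacts`)

Inputs: per-epoch `total_screen` (0.8–48 Hz) and gamma (32–48 Hz) log-power
series. For each epoch, the *context median* is the median over up to 10
epochs before and 10 after (±5 min), excluding the epoch itself (a spike
cannot mask itself) and truncated at the night boundaries. The night-level
threshold per series is `median − Q1` of the median-filtered series
(quartiles by linear interpolation — a data-driven spread measure that is
non-negative by construction and zero for a constant night). An epoch is
excluded when its value exceeds its context median by strictly more than the
threshold; the deviation is one-sided (positive excess) because the targeted
artifacts raise power (an absolute-deviation variant exists). Epochs carrying
annotated arousals or movements are excluded first.

Measured on synthetic nights at study scale (10 nights × 960 epochs):
sensitivity 1.00, false-positive rate 0.021 against the injected ground
truth.

## 4. Stage band powers (`somnomorph.bandpower`)

For each of stage N2 and REM, the per-epoch log band powers of the kept
(unmasked, in-bed) epochs are averaged on the log scale (default; the
mean-linear-then-log variant is available and is ≥ the log mean by Jensen's
inequality). NREM is restricted to N2 so differing NREM stage mixtures do
not leak into the comparison. A stage with zero kept epochs yields NaN and
`n_epochs_used = 0` — the value is never fabricated, and downstream
regressions drop that subject for that dependent only.

## 5. Morphometry (`somnomorph.morphometry`)

174 variables: 38 pinned subcortical segmentations (13 left/right pairs +
12 midline structures including the five corpus-callosum segments), plus
GrayVol and ThickAvg of the 34 Desikan–Killiany parcels per hemisphere.
ICV comes from the `EstimatedTotalIntraCranialVol` measure line of
`aseg.stats`. Extra segmentations are parsed and dropped; a missing retained
structure warns; duplicate structures, missing ICV, or comment-only files
are errors; a subject with any unparsable file is excluded with a warning
without affecting the column set.

## 6. Association engine (`somnomorph.association`)

Every test is `psg ~ 1 + morph + icv + age + sex` (OLS, statsmodels);
reported are the unstandardized slope of `morph`, `t = b/SE`, residual
df = n − 5, and the two-tailed p.

- **Hypothesis plan** (14 tests, raw p < .05): N2 delta1 and delta2 against
  left/right medial orbitofrontal volume, left/right posterior cingulate
  volume and anterior corpus callosum volume (10); TST against left/right
  hippocampal volume (2); and the two corpus-callosum tests repeated without
  the ICV covariate on subjects younger than 40 (2). df always follows the
  actual n and model size.
- **Explorative plan**: 39 sleep variables (11 continuity/architecture,
  8 event indices, 20 stage band powers) × 174 morphometric variables = 6786
  regressions; Benjamini–Hochberg FDR is applied separately within each
  dependent variable's 174 tests (step-up; equivalently
  `padj(i) = min_{j≥i} min(m·p(j)/j, 1)` on sorted p-values).
- Items with too few complete subjects, or with a rank-deficient design
  (e.g. a covariate constant in a subsample), produce a NaN row with a
  warning instead of aborting the run.
- Helpers: residual-method covariate adjustment (OLS residuals + grand
  mean), Fisher-Z mean correlation `tanh(mean(atanh r))`, ICV–age Pearson
  correlation and pooled-variance ICV-by-sex t-test.

## 7. Synthetic generator (`somnomorph.synthetic`)

All inputs the pipeline consumes are generated with recorded ground truth;
identical configurations (including seed) are bit-identical. Per-subject
streams use `default_rng([seed, subject_index, stream])`.

**Hypnogram** — first-order Markov chain over the five stages starting in
wake, row-stochastic transition matrix validated up front. The default
matrix produces consolidated bouts (self-transition 0.95–0.96, mean dwell
10–12 min) with N2 dominant — realistic bout structure matters because the
deviant-epoch screen's threshold measures exactly the night's slow
band-power spread. Nights are resampled (bounded retries) until N2 occurs;
a matrix that cannot reach N2 is rejected.

**EEG** — synthesized in the frequency domain: complex Gaussian rFFT
coefficients whose per-band variance realizes a stage-specific natural-log
band-power profile (N2/REM levels follow published all-night magnitudes;
W/N1/SWS are plausible interpolations; gamma is kept nearly stage-invariant
since large gamma excursions in referential EEG signal EMG contamination,
which is injected separately). Two slow log-power dynamics multiply all
bands jointly: an ultradian sinusoid (amplitude 0.80 ln-units, 90-min
period, random phase) and a smoothed random drift (0.30 ln-units) — these
give the screen's night-level threshold a realistic, non-degenerate spread.
Artifact epochs (rate 0.05) receive a whole-epoch burst at 40× the epoch's
modulated base variance, movement-like (0.3–1 Hz) or EMG-like (25–48 Hz)
with equal probability, and are recorded in the ground truth.

**Annotations** — Poisson counts at configured per-hour-of-TST or per-night
rates, placed uniformly on sleep epochs.

**Covariates** — age (clipped normal), sex (Bernoulli), ICV (normal with a
male mean shift), rounded to file precision.

**Morphometry** — each variable is a deterministic linear function of
ICV/age/sex (coefficients hashed stably from the variable name) plus
Gaussian noise; optional planted effects add `slope × psg_value` for chosen
(morph, psg) pairs, giving the association engine a recoverable ground
truth (95% CI coverage 0.93 over 200 replicates at slope 0.02). Values are
rounded to 4 decimals — the precision written into the FreeSurfer-format
stats files — so the write→parse round trip is exact.

**Not emulated**: real EEG waveform morphology (spindles, K-complexes, slow
waves as time-domain events), stage-transition semantics beyond first-order
Markov (no enforced NREM→REM cycling), within-epoch artifact bursts shorter
than an epoch, respiratory/cardiac physiology, scanner- or
segmentation-specific morphometry error structure, and any nonlinear
morphometry–sleep relationships.

## 8. Pipeline and determinism (`somnomorph.pipeline`, CLI)

Stages communicate via plain files under a run directory (covariates,
per-subject hypnogram/annotations/EEG/band series/mask, study-level metrics,
band powers, morphometry, regression tables, a YAML manifest with the full
configuration, and a run log). Any stage error aborts with the stage name
and subject id. Two runs with the same configuration produce byte-identical
TSV outputs; the full default study (38 × 960 epochs, both plans) takes
about 35 s on one CPU.

## 9. Known limitations

- n = 38 gives limited power; the explorative FDR yields a handful of
  significant rows even under the null in some seeds (BH controls the
  expected false-discovery proportion per dependent, not the study-wise
  count).
- The screen is tuned for whole-epoch power-raising artifacts; brief or
  power-lowering artifacts pass (the absolute-deviation variant catches the
  latter).
- WASO can be negative for nights with pre-onset sleep (literal SPT − TST
  identity, kept deliberately).
- The EDF reader requires the optional `mne` dependency; there is no EDF
  writer (synthetic signals persist as float32 `.npy`).
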