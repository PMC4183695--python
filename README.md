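# somnomorph

Sleep EEG spectral analysis meets brain morphometry: a reproducible pipeline
relating polysomnography-derived sleep variables to FreeSurfer-style brain
morphometry in a mass-univariate, covariate-adjusted regression design — with
a synthetic-data generator providing a full ground truth for every stage.

## What it computes

Studies of "brain structure vs. sleep" relate two very different data
sources. On the sleep side, an overnight EEG recording is scored into 30-s
epochs (the *hypnogram*), and each epoch's EEG is summarized by spectral band
powers. On the brain side, structural MRI is segmented into subcortical
volumes and cortical parcels. This package implements that whole analysis
chain:

1. **Sleep metrics** (`somnomorph.hypnogram`) — sleep onset latency, total
   sleep time (TST), sleep period time (SPT), wake after sleep onset
   (WASO = SPT − TST, exact by construction), sleep efficiency, awakenings,
   stage percentages of SPT, and event indices (arousals, PLMS,
   apnea/hypopnea per hour of TST), plus a good-sleeper eligibility screen.
2. **Spectral engine** (`somnomorph.spectral`) — per-epoch power spectra at
   200 Hz: 512-point windows overlapping by half (22 per 30-s epoch), linear
   detrend, parabolic Welch taper, one-sided power on a 0.390625-Hz grid;
   natural-log band powers over half-open bands delta1 (0.1–1 Hz) through
   gamma (32–48 Hz).
3. **Deviant-epoch screen** (`somnomorph.artifacts`) — excludes epochs whose
   broadband (0.8–48 Hz) or gamma log power exceeds a ±5-min median-filtered
   context by more than a night-level threshold (median − first quartile of
   the median-filtered series); annotated arousal/movement epochs are
   excluded first.
4. **Stage band powers** (`somnomorph.bandpower`) — all-night mean log band
   power over the kept epochs of stage N2 and of REM: 2 × 10 = 20 spectral
   variables per night.
5. **Morphometry** (`somnomorph.morphometry`) — parses `aseg.stats` and
   `lh/rh.aparc.stats` into 38 subcortical volumes + 68 cortical volumes +
   68 cortical thicknesses = 174 variables, with ICV from the measure line.
6. **Associations** (`somnomorph.association`) — OLS of each sleep variable
   on each morphometric variable with ICV, age and sex as covariates
   (df = n − 5; 33 at n = 38). A 14-test a-priori hypothesis plan, and an
   explorative plan of 39 × 174 = 6786 regressions with Benjamini–Hochberg
   FDR applied within each dependent variable.
7. **Synthetic study** (`somnomorph.synthetic`) — Markov-chain hypnograms,
   stage-dependent EEG synthesized in the frequency domain (with ultradian
   and drift log-power dynamics and injected movement/EMG artifact epochs),
   event annotations, covariates, and morphometry written as FreeSurfer-format
   stats files — all with recorded ground truth and optional planted
   morphometry–sleep effects.
8. **Pipeline + CLI** (`somnomorph.pipeline`, `somnomorph.cli`) — file-mediated
   stages under one run directory; byte-identical outputs under a fixed seed.

See `docs/methods.md` for definitions, parameters and design decisions.

## Command-line usage

```bash
# full synthetic study in one pass (38 subjects x 960 epochs by default)
somnomorph all --seed 1 --out run/

# or stage by stage (each stage re-runnable in isolation)
somnomorph simulate  --seed 1 --out run/
somnomorph metrics   --dir run/
somnomorph spectra   --dir run/
somnomorph screen    --dir run/
somnomorph aggregate --dir run/
somnomorph associate --dir run/
```

`--config config.yaml` overrides simulation/analysis defaults (cohort size,
transition matrix, artifact rate, planted effects, plans, …).

## Worked example

```python
import numpy as np
from somnomorph import (Hypnogram, compute_sleep_metrics, epoch_spectrum,
                        band_power)

h = Hypnogram(stages=("W", "W", "N2", "N2", "N1", "SWS", "W", "W",
                      "REM", "REM", "N2", "W", "N2", "W", "W", "W"))
m = compute_sleep_metrics(h)
print(m.sol_min, m.spt_min, m.tst_min, m.waso_min, m.sleep_efficiency_pct)
# 1.0 5.5 4.0 1.5 50.0

spec = epoch_spectrum(np.sin(2 * np.pi * 10.0 * np.arange(6000) / 200.0))
print(round(np.exp(band_power(spec, "alpha")) / np.exp(spec.log_power[1:]).sum().item(), 4))
# 0.9999  (a 10-Hz sinusoid lands almost entirely in the alpha band)
```

End-to-end in Python:

```python
from somnomorph import RunConfig, SimConfig, run

result = run(RunConfig(sim=SimConfig(seed=1)))
print(result.psg_table["n2_total"].mean())        # ~5.31 (ln uV^2 scale)
print(len(result.regressions["explorative"]))     # 6786
```

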