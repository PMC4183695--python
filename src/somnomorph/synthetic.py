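"""Synthetic polysomnography and morphometry with known ground truth.

Generates every input the analysis pipeline consumes — Markov-chain
hypnograms, stage-dependent single-channel EEG, event annotations,
FreeSurfer-format stats files and covariates — so each downstream stage is
testable without real recordings.

EEG epochs are synthesized in the frequency domain: complex Gaussian rFFT
coefficients whose per-band variance matches a stage-specific natural-log
band-power profile, so the spectral engine recovers the profile up to
estimation noise and band-edge leakage.  Artifact epochs additionally
receive a whole-epoch high-amplitude burst, either low-frequency
(0.3-1 Hz, movement-like) or high-frequency (25-48 Hz, EMG-like), and are
recorded in the ground truth.

Morphometric variables are linear functions of the covariates (ICV, age,
sex) plus Gaussian noise; optional planted effects add a known slope on a
polysomnographic variable, giving the association engine a recoverable
ground truth.  Values are rounded to the precision written into the stats
files, so a write-parse round trip is exact.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hypnogram import (
    EventAnnotations,
    Hypnogram,
    LegMovement,
    RespiratoryEvent,
    STAGES,
)
from .morphometry import (
    ASEG_STRUCTURES,
    DESIKAN_PARCELS,
    HEMISPHERES,
    MORPH_COLUMNS,
)
from .spectral import CANONICAL_BANDS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CovariateModel",
    "EventRates",
    "InvalidConfigError",
    "DEFAULT_TRANSITION",
    "DEFAULT_STAGE_BAND_PROFILE",
    "generate_hypnogram",
    "generate_eeg",
    "generate_annotations",
    "generate_covariates",
    "generate_morphometry",
    "morphometry_baseline",
    "write_aseg_stats",
    "write_aparc_stats",
    "write_subject_stats",
]

PROFILE_BANDS: tuple[str, ...] = (
    "delta1", "delta2", "theta", "alpha", "sigma1", "sigma2", "beta1", "beta2", "gamma",
)

#: Row-stochastic stage transition matrix over (W, N1, N2, SWS, REM).
#: Self-transition probabilities give consolidated bouts (mean dwell roughly
#: 10 min in wake/N2/SWS and 12 min in REM) with N2 as the dominant stage of
#: the stationary distribution.
DEFAULT_TRANSITION: np.ndarray = np.array(
    [
        # W      N1     N2     SWS    REM
        [0.950, 0.035, 0.015, 0.000, 0.000],  # W
        [0.050, 0.760, 0.190, 0.000, 0.000],  # N1
        [0.008, 0.010, 0.950, 0.016, 0.016],  # N2
        [0.003, 0.003, 0.044, 0.950, 0.000],  # SWS
        [0.010, 0.015, 0.015, 0.000, 0.960],  # REM
    ]
)

#: Natural-log band-power targets per stage.  N2 and REM follow the order of
#: magnitude of all-night sleep-EEG band powers reported for healthy adults;
#: W, N1 and SWS are plausible interpolations (alpha-rich wake, delta-dominant
#: SWS).  Gamma is kept nearly stage-invariant: in artifact-free referential
#: EEG, high-frequency power differs little between stages — large gamma
#: excursions are the signature of EMG contamination, which is injected
#: separately as an artifact.
DEFAULT_STAGE_BAND_PROFILE: dict[str, dict[str, float]] = {
    "W":   dict(zip(PROFILE_BANDS, (3.50, 3.00, 2.50, 2.80, 0.80, 0.50, 1.20, 0.30, -1.20))),
    "N1":  dict(zip(PROFILE_BANDS, (3.90, 3.60, 3.20, 2.20, 0.80, 0.30, 0.90, -0.20, -1.50))),
    "N2":  dict(zip(PROFILE_BANDS, (4.61, 4.24, 3.53, 2.75, 1.56, 0.63, 0.79, -0.38, -1.75))),
    "SWS": dict(zip(PROFILE_BANDS, (5.30, 4.80, 3.60, 2.40, 1.20, 0.40, 0.50, -0.70, -1.90))),
    "REM": dict(zip(PROFILE_BANDS, (3.17, 3.14, 2.84, 1.93, 0.43, 0.16, 1.02, -0.02, -1.62))),
}


class InvalidConfigError(ValueError):
    """Simulation configuration cannot produce a valid study input."""


@dataclass(frozen=True)
class CovariateModel:
    """Age/sex/ICV distributions; men get an ICV mean shift (in mm^3)."""

    age_mean: float = 39.6
    age_sd: float = 8.9
    age_range: tuple[float, float] = (25.0, 60.0)
    male_fraction: float = 17 / 38
    icv_female_mean: float = 1.031e6
    icv_male_mean: float = 1.160e6
    icv_sd: float = 6.5e4


@dataclass(frozen=True)
class EventRates:
    """Per-night event generation rates (indices per hour of TST or counts)."""

    arousals_per_h_tst: float = 14.2
    movements_per_night: float = 5.0
    leg_movements_per_night: float = 39.0
    p_plms: float = 0.37
    p_leg_arousal: float = 0.13
    respiratory_per_h_tst: float = 3.6
    p_apnea: float = 0.11


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a synthetic study.

    Identical configurations (including ``seed``) produce bit-identical
    hypnograms, signals, annotations, files and ground truth.
    """

    n_subjects: int = 38
    n_epochs: int = 960  # 8 h of 30-s epochs
    sampling_rate: float = 200.0
    epoch_seconds: float = 30.0
    stage_transition: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITION.copy())
    stage_band_profile: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_STAGE_BAND_PROFILE.items()}
    )
    artifact_rate: float = 0.05
    artifact_gain: float = 40.0  # burst variance as a multiple of the epoch's base variance
    # slow within-night log-power dynamics (set both amplitudes to 0 for
    # strictly stationary stage profiles)
    ultradian_amplitude: float = 0.80  # natural-log units, ~90-min cycle
    ultradian_period_min: float = 90.0
    drift_amplitude: float = 0.30  # natural-log units, smoothed random drift
    planted_effects: tuple[tuple[str, str, float], ...] = ()
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    event_rates: EventRates = field(default_factory=EventRates)
    morph_noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        trans = np.asarray(self.stage_transition, dtype=float)
        if trans.shape != (5, 5):
            raise InvalidConfigError(f"stage_transition must be 5x5, got {trans.shape}")
        if np.any(trans < 0) or np.any(np.abs(trans.sum(axis=1) - 1.0) > 1e-12):
            raise InvalidConfigError("stage_transition rows must be non-negative and sum to 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise InvalidConfigError(f"artifact_rate must be in [0, 1], got {self.artifact_rate}")
        if self.n_epochs < 20:
            raise InvalidConfigError("n_epochs must be >= 20 (the artifact screen needs context)")
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        for morph, _, _ in self.planted_effects:
            if morph not in MORPH_COLUMNS:
                raise InvalidConfigError(
                    f"planted morphometric variable {morph!r} is not one of the 174 "
                    f"canonical names: {sorted(MORPH_COLUMNS)}"
                )

    @property
    def epoch_samples(self) -> int:
        return int(round(self.sampling_rate * self.epoch_seconds))


@dataclass
class GroundTruth:
    """What was actually injected into one synthetic night."""

    true_artifact_epochs: set[int] = field(default_factory=set)
    artifact_kinds: dict[int, str] = field(default_factory=dict)  # epoch -> 'movement'|'emg'
    true_stage_sequence: tuple[str, ...] = ()
    true_slopes: tuple[tuple[str, str, float], ...] = ()


def subject_rng(cfg: SimConfig, subject_index: int, stream: int) -> np.random.Generator:
    """Deterministic per-subject, per-stage random generator."""
    return np.random.default_rng([cfg.seed, subject_index, stream])


def generate_hypnogram(cfg: SimConfig, rng: Optional[np.random.Generator] = None,
                       max_retries: int = 20) -> Hypnogram:
    """Sample a Markov-chain stage sequence starting in wake.

    Lights out is epoch 0 and lights on is ``n_epochs``.  The night is
    resampled (bounded retries) until it contains at least one N2 epoch;
    a transition matrix that cannot reach N2 raises ``InvalidConfigError``.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    trans = np.asarray(cfg.stage_transition, dtype=float)
    cum = np.cumsum(trans, axis=1)
    for _ in range(max_retries):
        states = np.empty(cfg.n_epochs, dtype=np.int64)
        state = 0  # W
        states[0] = state
        u = rng.random(cfg.n_epochs)
        for i in range(1, cfg.n_epochs):
            state = int(np.searchsorted(cum[state], u[i], side="right"))
            states[i] = state
        stages = tuple(STAGES[s] for s in states)
        if "N2" in stages:
            return Hypnogram(stages=stages, epoch_seconds=cfg.epoch_seconds,
                             lights_out_epoch=0, lights_on_epoch=cfg.n_epochs)
    raise InvalidConfigError(
        f"no N2 epoch generated in {max_retries} attempts; "
        "the transition matrix cannot reach stage N2 from wake"
    )


def _band_bin_variances(cfg: SimConfig, profile: dict[str, float],
                        freqs: np.ndarray) -> np.ndarray:
    """Per-rFFT-bin signal variance realizing the stage's log band powers."""
    var = np.zeros_like(freqs)
    for band_name, level in profile.items():
        band = CANONICAL_BANDS[band_name]
        idx = np.nonzero((freqs >= band.low) & (freqs < band.high))[0]
        if idx.size:
            var[idx] = np.exp(level) / idx.size
    return var


def _band_noise(rng: np.random.Generator, n_epochs: int, n_samples: int,
                bin_var: np.ndarray) -> np.ndarray:
    """Gaussian signals with the given per-rFFT-bin variance, (n_epochs, n_samples)."""
    n_bins = n_samples // 2 + 1
    # x = irfft(Z): var(x) = (4 / n^2) * sum(sd_k^2) for interior bins
    sd = (n_samples / 2.0) * np.sqrt(bin_var)
    z = sd * (rng.standard_normal((n_epochs, n_bins)) + 1j * rng.standard_normal((n_epochs, n_bins)))
    z[:, 0] = 0.0
    z[:, -1] = 0.0
    return np.fft.irfft(z, n=n_samples, axis=1)


def generate_eeg(
    h: Hypnogram, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesize one night of per-epoch EEG plus its ground truth.

    Returns
    -------
    signals : (n_epochs, epoch_samples) float array
    truth : GroundTruth with the injected artifact epochs and kinds
    """
    cfg.validate()
    if len(h) != cfg.n_epochs:
        raise ValueError(f"hypnogram length {len(h)} != cfg.n_epochs {cfg.n_epochs}")
    if abs(cfg.sampling_rate - 200.0) > 1e-9:
        warnings.warn(
            f"sampling_rate {cfg.sampling_rate} Hz differs from the spectral engine "
            "default (200 Hz); signals generated anyway",
            stacklevel=2,
        )
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, n_samp = cfg.n_epochs, cfg.epoch_samples
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / cfg.sampling_rate)
    signals = np.empty((n, n_samp))
    stage_arr = np.array(h.stages)
    base_var = np.empty(n)
    for stage in STAGES:
        sel = np.nonzero(stage_arr == stage)[0]
        if sel.size == 0:
            continue
        bin_var = _band_bin_variances(cfg, cfg.stage_band_profile[stage], freqs)
        signals[sel] = _band_noise(rng, sel.size, n_samp, bin_var)
        base_var[sel] = bin_var.sum()

    # slow within-night dynamics: an ultradian cycle plus a smoothed random
    # drift modulate the log power of all bands jointly, as real all-night
    # band-power series do; the night-level rejection threshold of the
    # deviant-epoch screen measures exactly this spread.
    mod = np.zeros(n)
    if cfg.ultradian_amplitude > 0:
        period_epochs = cfg.ultradian_period_min * 60.0 / cfg.epoch_seconds
        phase = rng.uniform(0.0, 2.0 * np.pi)
        mod += cfg.ultradian_amplitude * np.sin(2.0 * np.pi * np.arange(n) / period_epochs + phase)
    if cfg.drift_amplitude > 0:
        white = rng.standard_normal(n + 20)
        smooth = np.convolve(white, np.ones(21) / 21.0, mode="valid")
        mod += cfg.drift_amplitude * smooth / max(float(smooth.std()), 1e-12)
    signals *= np.exp(mod / 2.0)[:, None]
    base_var *= np.exp(mod)

    truth = GroundTruth(true_stage_sequence=h.stages, true_slopes=cfg.planted_effects)
    if cfg.artifact_rate > 0:
        artifact = np.nonzero(rng.random(n) < cfg.artifact_rate)[0]
        kinds = rng.random(artifact.size) < 0.5
        for epoch, is_movement in zip(artifact, kinds):
            lo, hi = (0.3, 1.0) if is_movement else (25.0, 48.0)
            idx = np.nonzero((freqs >= lo) & (freqs < hi))[0]
            bin_var = np.zeros_like(freqs)
            bin_var[idx] = cfg.artifact_gain * base_var[epoch] / idx.size
            signals[epoch] += _band_noise(rng, 1, n_samp, bin_var)[0]
            truth.true_artifact_epochs.add(int(epoch))
            truth.artifact_kinds[int(epoch)] = "movement" if is_movement else "emg"
    return signals, truth


def generate_annotations(
    h: Hypnogram, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> EventAnnotations:
    """Draw arousal, movement, leg-movement and respiratory annotations.

    Events are placed uniformly on the night's sleep epochs with Poisson
    counts at the configured rates (per hour of total sleep time where the
    rate is an index).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rates = cfg.event_rates
    sleep_epochs = np.nonzero(np.array(h.stages) != "W")[0]
    if sleep_epochs.size == 0:
        return EventAnnotations()
    tst_h = sleep_epochs.size * h.epoch_seconds / 3600.0

    def draw(count: int) -> np.ndarray:
        return rng.choice(sleep_epochs, size=count, replace=True)

    arousals = sorted(int(i) for i in draw(rng.poisson(rates.arousals_per_h_tst * tst_h)))
    movements = sorted(int(i) for i in draw(rng.poisson(rates.movements_per_night)))
    n_lm = rng.poisson(rates.leg_movements_per_night)
    leg = [
        LegMovement(
            epoch_index=int(e),
            with_arousal=bool(rng.random() < rates.p_leg_arousal),
            is_plms=bool(rng.random() < rates.p_plms),
        )
        for e in draw(n_lm)
    ]
    n_resp = rng.poisson(rates.respiratory_per_h_tst * tst_h)
    resp = [
        RespiratoryEvent(epoch_index=int(e), is_apnea=bool(rng.random() < rates.p_apnea))
        for e in draw(n_resp)
    ]
    return EventAnnotations(arousals=arousals, movements=movements,
                            leg_movements=leg, respiratory_events=resp)


def generate_covariates(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Subject covariates: age (years), sex (0 = female, 1 = male), ICV (mm^3)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    m = cfg.covariate_model
    n = cfg.n_subjects
    age = np.clip(rng.normal(m.age_mean, m.age_sd, size=n), *m.age_range)
    sex = (rng.random(n) < m.male_fraction).astype(int)
    icv_mean = np.where(sex == 1, m.icv_male_mean, m.icv_female_mean)
    icv = rng.normal(icv_mean, m.icv_sd)
    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {"age": np.round(age, 1), "sex": sex, "icv": np.round(icv, 1)},
        index=pd.Index(subjects, name="subject"),
    )


def _variable_params(name: str) -> dict[str, float]:
    """Deterministic per-variable generative coefficients (stable name hash)."""
    r = np.random.default_rng(zlib.crc32(name.encode()))
    if name.endswith("_thickness"):
        return {
            "kind": 1.0,
            "base": r.uniform(2.0, 3.0),
            "icv_coef": 0.0,
            "age_coef": -0.010,  # mm per year
            "sex_coef": r.uniform(-0.05, 0.05),
            "noise_sd": 0.08,
        }
    icv_coef = float(np.exp(r.uniform(np.log(2e-4), np.log(5e-3))))
    typical = icv_coef * 1.09e6
    return {
        "kind": 0.0,
        "base": 0.0,
        "icv_coef": icv_coef,
        "age_coef": -0.004 * typical,  # mild atrophy with age
        "sex_coef": r.uniform(-0.01, 0.01) * typical,
        "noise_sd": 0.05 * typical,
    }


def morphometry_baseline(covariates: pd.DataFrame) -> pd.DataFrame:
    """Covariate-determined morphometry table without noise or planted effects."""
    out = {}
    age = covariates["age"].to_numpy(float)
    sex = covariates["sex"].to_numpy(float)
    icv = covariates["icv"].to_numpy(float)
    for name in MORPH_COLUMNS:
        p = _variable_params(name)
        out[name] = p["base"] + p["icv_coef"] * icv + p["age_coef"] * (age - 40.0) + p["sex_coef"] * sex
    return pd.DataFrame(out, index=covariates.index).round(4)


def generate_morphometry(
    cfg: SimConfig,
    covariates: pd.DataFrame,
    psg_table: Optional[pd.DataFrame] = None,
    out_dir: Optional[Path] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Generate the 174-variable morphometry table and optional stats files.

    Planted effects ``(morph_variable, psg_variable, slope)`` add
    ``slope * psg_value`` on top of the covariate-determined baseline;
    ``psg_table`` must then carry the referenced variable.  Values are
    rounded to 4 decimals, the precision written into the stats files, so a
    write-parse round trip through :mod:`somnomorph.morphometry` is exact.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 777])
    table = morphometry_baseline(covariates)
    for name in MORPH_COLUMNS:
        p = _variable_params(name)
        table[name] = table[name] + cfg.morph_noise_scale * rng.normal(
            0.0, p["noise_sd"], size=len(table)
        )
    for morph, psg, slope in cfg.planted_effects:
        if psg_table is None or psg not in psg_table.columns:
            raise InvalidConfigError(
                f"planted effect references PSG variable {psg!r} absent from psg_table"
            )
        y = psg_table.reindex(table.index)[psg].to_numpy(float)
        table[morph] = table[morph] + slope * y
    table = table.round(4)
    # thicknesses and volumes must stay physical
    for name in MORPH_COLUMNS:
        lower = 0.1 if name.endswith("_thickness") else 1.0
        table[name] = table[name].clip(lower=lower)
    if out_dir is not None:
        for subject, row in table.iterrows():
            write_subject_stats(
                Path(out_dir) / str(subject) / "stats",
                row,
                icv=float(covariates.loc[subject, "icv"]),
            )
    return table


def write_aseg_stats(path: Path, volumes: dict[str, float], icv: float) -> None:
    """Write a subcortical-segmentation stats file (synthetic data)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        "# Title synthetic aseg.stats (somnomorph synthetic data)",
        f"# Measure EstimatedTotalIntraCranialVol, eTIV, Estimated Total Intracranial Volume, {icv:.4f}, mm^3",
        "# ColHeaders Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax",
    ]
    for i, (name, vol) in enumerate(volumes.items(), start=1):
        lines.append(f"{i:3d} {i:4d} {int(round(vol)):8d} {vol:12.4f} {name:<32s} 0.0 0.0 0.0 0.0")
    path.write_text("\n".join(lines) + "\n")


def write_aparc_stats(path: Path, hemisphere: str,
                      parcels: dict[str, tuple[float, float]]) -> None:
    """Write a cortical-parcellation stats file (synthetic data)."""
    if hemisphere not in HEMISPHERES:
        raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"# Title synthetic {hemisphere}.aparc.stats (somnomorph synthetic data)",
        f"# hemi {hemisphere}",
        "# ColHeaders StructName NumVert SurfArea GrayVol ThickAvg ThickStd MeanCurv GausCurv FoldInd CurvInd",
    ]
    for name, (vol, thick) in parcels.items():
        lines.append(
            f"{name:<28s} {int(round(vol / 3)):7d} {vol / 2:10.1f} {vol:12.4f} "
            f"{thick:8.4f} 0.4000 0.10 0.02 10 1.0"
        )
    path.write_text("\n".join(lines) + "\n")


def write_subject_stats(stats_dir: Path, morph_row: pd.Series, icv: float) -> None:
    """Write aseg.stats + lh/rh aparc.stats for one subject from a table row."""
    stats_dir = Path(stats_dir)
    write_aseg_stats(
        stats_dir / "aseg.stats",
        {name: float(morph_row[name]) for name in ASEG_STRUCTURES},
        icv=icv,
    )
    for hemi in HEMISPHERES:
        parcels = {
            p: (float(morph_row[f"{hemi}_{p}_volume"]), float(morph_row[f"{hemi}_{p}_thickness"]))
            for p in DESIKAN_PARCELS
        }
        write_aparc_stats(stats_dir / f"{hemi}.aparc.stats", hemi, parcels)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of the configuration with a different seed."""
    return replace(cfg, seed=seed)
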