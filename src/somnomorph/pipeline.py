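"""End-to-end orchestration: simulate -> metrics -> spectra -> screen ->
aggregate -> associate, as a configured, logged, reproducible run.

Stages communicate via plain files under the run directory, so any stage can
be re-run in isolation:

    <out>/covariates.tsv
    <out>/<subject>/hypnogram.csv        (epoch_index, stage)
    <out>/<subject>/annotations.csv      (event_type, epoch_index, flags)
    <out>/<subject>/eeg.npy              (n_epochs x epoch_samples, float32)
    <out>/<subject>/band_series.tsv      (per-epoch screening series)
    <out>/<subject>/mask.csv             (epoch_index, keep, reason)
    <out>/metrics.tsv, band_power.tsv, morphometry.tsv
    <out>/stats/<subject>/{aseg.stats, lh.aparc.stats, rh.aparc.stats}
    <out>/regressions_hypothesis.tsv, regressions_explorative.tsv
    <out>/manifest.yaml

A full run is deterministic under a fixed seed: identical configuration
yields byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .artifacts import ExclusionMask, screen_epochs
from .association import explorative_plan, hypothesis_plan, run_plan
from .bandpower import AGGREGATED_STAGES, StageBandPower, aggregate, band_power_table
from .hypnogram import (
    EventAnnotations,
    Hypnogram,
    LegMovement,
    RespiratoryEvent,
    compute_sleep_metrics,
)
from .morphometry import assemble
from .spectral import SpectralConfig, band_power_series, epoch_spectra
from .synthetic import (
    SimConfig,
    generate_annotations,
    generate_covariates,
    generate_eeg,
    generate_hypnogram,
    generate_morphometry,
    subject_rng,
)

__all__ = ["RunConfig", "RunResult", "run", "process_night",
           "save_annotations", "load_annotations"]

log = logging.getLogger("somnomorph")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (simulate mode)."""

    sim: SimConfig = field(default_factory=SimConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    screening: bool = True
    plans: tuple[str, ...] = ("hypothesis", "explorative")
    out_dir: Optional[Path] = None
    write_eeg: bool = False  # per-subject .npy signals (large)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["stage_transition"] = np.asarray(self.sim.stage_transition).tolist()
        d["out_dir"] = str(self.out_dir) if self.out_dir else None
        return d


@dataclass
class RunResult:
    metrics: pd.DataFrame
    band_power: pd.DataFrame
    psg_table: pd.DataFrame
    morph_table: pd.DataFrame
    regressions: dict[str, pd.DataFrame]
    masks: dict[str, ExclusionMask]
    ground_truth: dict[str, object]


def save_annotations(path: Path, ann: EventAnnotations) -> None:
    rows = [("arousal", i, "", "") for i in ann.arousals]
    rows += [("movement", i, "", "") for i in ann.movements]
    rows += [("leg_movement", e.epoch_index, int(e.with_arousal), int(e.is_plms))
             for e in ann.leg_movements]
    rows += [("respiratory", e.epoch_index, int(e.is_apnea), "")
             for e in ann.respiratory_events]
    pd.DataFrame(rows, columns=["event_type", "epoch_index", "flag1", "flag2"]).to_csv(
        path, index=False
    )


def load_annotations(path: Path) -> EventAnnotations:
    df = pd.read_csv(path, dtype={"event_type": str}, keep_default_na=False)
    ann = EventAnnotations(arousals=[], movements=[], leg_movements=[], respiratory_events=[])
    for _, row in df.iterrows():
        kind, idx = row["event_type"], int(row["epoch_index"])
        if kind == "arousal":
            ann.arousals.append(idx)
        elif kind == "movement":
            ann.movements.append(idx)
        elif kind == "leg_movement":
            ann.leg_movements.append(
                LegMovement(idx, with_arousal=bool(int(row["flag1"])),
                            is_plms=bool(int(row["flag2"])))
            )
        elif kind == "respiratory":
            ann.respiratory_events.append(RespiratoryEvent(idx, is_apnea=bool(int(row["flag1"]))))
        else:
            raise ValueError(f"{path}: unknown event_type {kind!r}")
    return ann


def process_night(
    h: Hypnogram,
    signals: np.ndarray,
    ann: EventAnnotations,
    spectral_cfg: SpectralConfig,
    screening: bool = True,
):
    """Spectra, screening mask, sleep metrics and stage band powers of one night."""
    log_power = epoch_spectra(signals, spectral_cfg)
    mask = None
    if screening:
        total = band_power_series(log_power, "total_screen", spectral_cfg)
        gamma = band_power_series(log_power, "gamma", spectral_cfg)
        mask = screen_epochs(total, gamma, ann)
    metrics = compute_sleep_metrics(h, ann)
    stage_powers: dict[str, StageBandPower] = {
        stage: aggregate(log_power, h, mask, stage, cfg=spectral_cfg)
        for stage in AGGREGATED_STAGES
    }
    return log_power, mask, metrics, stage_powers


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run(cfg: RunConfig) -> RunResult:
    """Execute the full synthetic study and write all artifacts.

    Each stage error aborts the run with the stage name and subject id in the
    exception message.
    """
    cfg.sim.validate()
    out = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        return _run_inner(cfg, out)
    finally:
        if out is not None:
            log.removeHandler(handler)
            handler.close()


def _run_inner(cfg: RunConfig, out: Optional[Path]) -> RunResult:
    sim = cfg.sim
    covariates = generate_covariates(sim, np.random.default_rng([sim.seed, 999]))
    subjects = list(covariates.index)
    log.info("simulating %d subjects x %d epochs (seed %d)", sim.n_subjects, sim.n_epochs, sim.seed)

    metrics_rows, per_subject_power = {}, {}
    masks: dict[str, ExclusionMask] = {}
    truths: dict[str, object] = {}
    for i, subject in enumerate(subjects):
        stage = "hypnogram"
        try:
            h = generate_hypnogram(sim, subject_rng(sim, i, 0))
            stage = "annotations"
            ann = generate_annotations(h, sim, subject_rng(sim, i, 1))
            stage = "eeg"
            signals, truth = generate_eeg(h, sim, subject_rng(sim, i, 2))
            stage = "spectra/screen/aggregate"
            _, mask, metrics, stage_powers = process_night(
                h, signals, ann, cfg.spectral, cfg.screening
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed for subject {subject!r}: {exc}") from exc
        metrics_rows[subject] = metrics.as_dict()
        per_subject_power[subject] = stage_powers
        masks[subject] = mask
        truths[subject] = truth
        if out is not None:
            sdir = out / subject
            sdir.mkdir(exist_ok=True)
            h.to_frame().to_csv(sdir / "hypnogram.csv", index=False)
            save_annotations(sdir / "annotations.csv", ann)
            if cfg.write_eeg:
                np.save(sdir / "eeg.npy", signals.astype(np.float32))
            if mask is not None:
                mask.to_frame().to_csv(sdir / "mask.csv", index=False)
        del signals

    metrics_df = pd.DataFrame.from_dict(metrics_rows, orient="index").rename_axis("subject")
    power_df = band_power_table(per_subject_power)
    psg_table = metrics_df.join(power_df)

    stats_root = out / "stats" if out is not None else None
    morph_values = generate_morphometry(
        sim, covariates, psg_table=psg_table, out_dir=stats_root,
        rng=np.random.default_rng([sim.seed, 777]),
    )
    if stats_root is not None:
        # read the written stats files back through the parser
        morph_table = assemble(
            {s: stats_root / s / "stats" for s in subjects}, covariates=covariates
        )
    else:
        morph_table = morph_values.join(covariates)

    regressions: dict[str, pd.DataFrame] = {}
    for plan_name in cfg.plans:
        plan = hypothesis_plan() if plan_name == "hypothesis" else explorative_plan()
        log.info("running %s plan (%d regressions)", plan_name, len(plan))
        regressions[plan_name] = run_plan(plan, psg_table, morph_table)

    if out is not None:
        _write_tsv(covariates, out / "covariates.tsv")
        _write_tsv(metrics_df, out / "metrics.tsv")
        _write_tsv(power_df, out / "band_power.tsv")
        _write_tsv(morph_table, out / "morphometry.tsv")
        for name, df in regressions.items():
            _write_tsv(df, out / f"regressions_{name}.tsv", index=False)
        manifest = {
            "package": "somnomorph",
            "version": __version__,
            "seed": sim.seed,
            "config": json.loads(json.dumps(cfg.to_dict(), default=str)),
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return RunResult(
        metrics=metrics_df,
        band_power=power_df,
        psg_table=psg_table,
        morph_table=morph_table,
        regressions=regressions,
        masks=masks,
        ground_truth=truths,
    )
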