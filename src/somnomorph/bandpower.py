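"""All-night, stage-conditional spectral band-power variables.

For every artifact-free epoch of a given stage, the per-epoch natural-log
band power (log of summed linear bin power) is computed for the ten reported
bands; those log values are then averaged across the kept epochs.  NREM is
restricted to stage N2 to remove the influence of differing NREM stage
distributions across subjects, and REM is aggregated separately, giving
2 stages x 10 bands = 20 spectral variables per night.

Averaging on the log scale is the default; averaging linear power before
taking the log is available via ``linear_mean=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .artifacts import ExclusionMask
from .hypnogram import Hypnogram
from .spectral import REPORTED_BANDS, SpectralConfig, band_bins

__all__ = ["StageBandPower", "AGGREGATED_STAGES", "aggregate", "band_power_table"]

#: Stages for which all-night band powers are reported.
AGGREGATED_STAGES: tuple[str, ...] = ("N2", "REM")


@dataclass
class StageBandPower:
    """Aggregated band powers of one stage of one night."""

    stage: str
    values: dict[str, float]  # band name -> mean log band power (NaN if no epochs)
    n_epochs_used: int


def aggregate(
    log_power: np.ndarray,
    h: Hypnogram,
    mask: ExclusionMask | None,
    stage: str,
    bands: tuple[str, ...] = REPORTED_BANDS,
    cfg: SpectralConfig | None = None,
    linear_mean: bool = False,
) -> StageBandPower:
    """Average per-epoch log band powers over the kept epochs of one stage.

    Parameters
    ----------
    log_power : (n_epochs, n_bins) array
        Per-epoch log power spectra, aligned with the hypnogram.
    mask : ExclusionMask or None
        Artifact screen output; None keeps every epoch.
    stage : 'N2' or 'REM'
    linear_mean : bool
        Average linear band power across epochs before the final log, instead
        of averaging the per-epoch log values (the default).

    A stage with zero kept epochs yields NaN values and ``n_epochs_used=0``;
    the subject is flagged downstream rather than a value fabricated.
    """
    if stage not in AGGREGATED_STAGES:
        raise ValueError(f"stage must be one of {AGGREGATED_STAGES}, got {stage!r}")
    cfg = cfg or SpectralConfig()
    log_power = np.asarray(log_power, dtype=float)
    if log_power.shape[0] != len(h):
        raise ValueError(
            f"spectra/hypnogram length mismatch: {log_power.shape[0]} vs {len(h)}"
        )
    keep = np.ones(len(h), dtype=bool) if mask is None else np.asarray(mask.keep, dtype=bool)
    if keep.size != len(h):
        raise ValueError("mask length does not match hypnogram")

    stage_arr = np.array(h.stages)
    in_bed = np.zeros(len(h), dtype=bool)
    in_bed[h.lights_out_epoch : h.lights_on_epoch] = True
    sel = (stage_arr == stage) & keep & in_bed
    n_used = int(sel.sum())
    if n_used == 0:
        return StageBandPower(stage=stage, values={b: float("nan") for b in bands}, n_epochs_used=0)

    values: dict[str, float] = {}
    for band in bands:
        idx = band_bins(band, cfg.freqs)
        per_epoch_linear = np.exp(log_power[sel][:, idx]).sum(axis=1)
        per_epoch_linear = np.maximum(per_epoch_linear, cfg.log_floor)
        if linear_mean:
            values[band] = float(np.log(per_epoch_linear.mean()))
        else:
            values[band] = float(np.log(per_epoch_linear).mean())
    return StageBandPower(stage=stage, values=values, n_epochs_used=n_used)


def band_power_table(
    per_subject: dict[str, dict[str, StageBandPower]],
    bands: tuple[str, ...] = REPORTED_BANDS,
) -> pd.DataFrame:
    """Assemble subjects x 20 spectral variables (columns like ``rem_beta2``).

    ``per_subject`` maps subject id -> {stage -> StageBandPower}.  Epoch
    counts are carried in ``n_epochs_<stage>`` columns.
    """
    rows = []
    for subject, stages in per_subject.items():
        row: dict[str, float] = {"subject": subject}
        for stage in AGGREGATED_STAGES:
            sbp = stages.get(stage)
            prefix = stage.lower()
            for band in bands:
                row[f"{prefix}_{band}"] = sbp.values[band] if sbp is not None else float("nan")
            row[f"n_epochs_{prefix}"] = sbp.n_epochs_used if sbp is not None else 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")
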