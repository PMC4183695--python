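"""Data-driven exclusion of deviant sleep-EEG epochs.

Two per-epoch log-power series are screened: broadband (0.8-48 Hz) and gamma
(32-48 Hz).  Each epoch's value is compared with its median-filtered context
(the median over the 5 min preceding and 5 min following the epoch, i.e. up
to 10 epochs on each side at 30-s epochs, never the epoch itself).  An epoch
is excluded when its value exceeds the context median by more than a
night-level threshold: the difference between the median and the first
quartile of all median-filtered values across the night.  The broadband
series catches low-frequency artifacts (movement, ocular events); the gamma
series catches EMG contamination.  Epochs carrying annotated arousals or
movements are excluded outright before the data-driven rule runs.

The deviation is one-sided (positive excess) by default, since the targeted
artifacts raise power; an absolute-deviation variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExclusionMask",
    "CONTEXT_HALF_WINDOW",
    "context_median",
    "context_medians",
    "rejection_threshold",
    "screen_epochs",
]

#: 5 min of 30-s epochs on each side of the screened epoch.
CONTEXT_HALF_WINDOW = 10

KEEP = "none"
REASON_ANNOTATED = "annotated"
REASON_TOTAL = "deviant_total"
REASON_GAMMA = "deviant_gamma"


@dataclass
class ExclusionMask:
    """Per-epoch keep/drop decisions with reasons and screening diagnostics."""

    keep: np.ndarray  # bool per epoch
    reason: list[str]  # 'none' | 'annotated' | 'deviant_total' | 'deviant_gamma'
    threshold_total: float
    threshold_gamma: float
    context_total: np.ndarray = field(default=None)
    context_gamma: np.ndarray = field(default=None)

    @property
    def n_excluded(self) -> int:
        return int((~self.keep).sum())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"epoch_index": np.arange(self.keep.size), "keep": self.keep, "reason": self.reason}
        )


def context_median(series: np.ndarray, i: int, half_window: int = CONTEXT_HALF_WINDOW) -> float:
    """Median of up to ``half_window`` epochs before and after epoch ``i``.

    The epoch's own value is excluded so a spike cannot mask itself; the
    context is truncated at the night boundaries.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("context median needs a series of at least 2 epochs")
    if not 0 <= i < series.size:
        raise IndexError(f"epoch index {i} out of range for {series.size} epochs")
    lo = max(0, i - half_window)
    hi = min(series.size, i + half_window + 1)
    neighbours = np.concatenate([series[lo:i], series[i + 1 : hi]])
    return float(np.median(neighbours))


def context_medians(series: np.ndarray, half_window: int = CONTEXT_HALF_WINDOW) -> np.ndarray:
    """Median-filtered series: ``context_median`` at every epoch."""
    series = np.asarray(series, dtype=float)
    return np.array([context_median(series, i, half_window) for i in range(series.size)])


def rejection_threshold(context_meds: np.ndarray) -> float:
    """Night-level threshold: median minus first quartile of the median-filtered values.

    Quartiles use linear interpolation between order statistics.  Non-negative
    for any input.
    """
    context_meds = np.asarray(context_meds, dtype=float)
    if context_meds.size < 4:
        raise ValueError("rejection threshold needs at least 4 median-filtered values")
    med = float(np.median(context_meds))
    q1 = float(np.quantile(context_meds, 0.25, method="linear"))
    return med - q1


def screen_epochs(
    total_series: np.ndarray,
    gamma_series: np.ndarray,
    annotations=None,
    half_window: int = CONTEXT_HALF_WINDOW,
    absolute: bool = False,
) -> ExclusionMask:
    """Exclude annotated and deviant epochs from a night.

    Parameters
    ----------
    total_series, gamma_series : arrays, one value per epoch
        Per-epoch broadband (0.8-48 Hz) and gamma (32-48 Hz) log power.
    annotations : EventAnnotations, optional
        Epochs holding annotated arousals or movements are excluded with
        reason ``annotated`` before the data-driven screen.
    absolute : bool
        Screen on |deviation| instead of the (default) positive excess.

    Each series is screened against its own context medians and its own
    night-level threshold, computed over all epochs of the night.  Exclusion
    requires a strict exceedance, so a constant series excludes nothing.
    """
    total_series = np.asarray(total_series, dtype=float)
    gamma_series = np.asarray(gamma_series, dtype=float)
    if total_series.shape != gamma_series.shape:
        raise ValueError(
            f"series length mismatch: total {total_series.shape} vs gamma {gamma_series.shape}"
        )
    n = total_series.size
    keep = np.ones(n, dtype=bool)
    reason = [KEEP] * n

    annotated: set[int] = set()
    if annotations is not None:
        annotated = {int(i) for i in annotations.arousals} | {int(i) for i in annotations.movements}
        out_of_range = [i for i in annotated if not 0 <= i < n]
        if out_of_range:
            raise IndexError(f"annotated epochs out of range: {sorted(out_of_range)}")

    ctx_total = context_medians(total_series, half_window)
    ctx_gamma = context_medians(gamma_series, half_window)
    thr_total = rejection_threshold(ctx_total)
    thr_gamma = rejection_threshold(ctx_gamma)

    dev_total = total_series - ctx_total
    dev_gamma = gamma_series - ctx_gamma
    if absolute:
        dev_total = np.abs(dev_total)
        dev_gamma = np.abs(dev_gamma)

    for i in range(n):
        if i in annotated:
            keep[i] = False
            reason[i] = REASON_ANNOTATED
        elif dev_total[i] > thr_total:
            keep[i] = False
            reason[i] = REASON_TOTAL
        elif dev_gamma[i] > thr_gamma:
            keep[i] = False
            reason[i] = REASON_GAMMA

    return ExclusionMask(
        keep=keep,
        reason=reason,
        threshold_total=thr_total,
        threshold_gamma=thr_gamma,
        context_total=ctx_total,
        context_gamma=ctx_gamma,
    )
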