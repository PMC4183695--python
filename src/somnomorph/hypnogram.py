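"""Sleep continuity and architecture metrics from a 30-s-epoch hypnogram.

Definitions follow standard polysomnography conventions:

* sleep onset  — first epoch of stage N2 at or after lights out
* TST          — total sleep time: non-wake epochs between lights out and lights on
* SPT          — sleep period time: onset through the last non-wake epoch, inclusive
* WASO         — wake after sleep onset: SPT - TST (exact by construction)
* SE           — sleep efficiency: 100 * TST / time in bed
* awakenings   — maximal contiguous wake runs strictly inside the sleep period
* stage %      — stage time as a percentage of SPT

Event-based indices (arousal index, PLMS index, apnea-hypopnea index, ...)
are counts per hour of TST; the events themselves are consumed as
annotations, not detected here.  The eligibility screen rejects records with
a PLMS-arousal index or a sleep-apnea index strictly above 5.0/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "SLEEP_STAGES",
    "Hypnogram",
    "LegMovement",
    "RespiratoryEvent",
    "EventAnnotations",
    "SleepMetrics",
    "sleep_onset",
    "compute_sleep_metrics",
    "eligibility_screen",
]

STAGES: tuple[str, ...] = ("W", "N1", "N2", "SWS", "REM")
SLEEP_STAGES: tuple[str, ...] = ("N1", "N2", "SWS", "REM")


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage labels with lights-out/lights-on bounds.

    ``lights_out_epoch`` is inclusive, ``lights_on_epoch`` exclusive; epochs
    outside that interval are ignored by every metric.
    """

    stages: tuple[str, ...]
    epoch_seconds: float = 30.0
    lights_out_epoch: int = 0
    lights_on_epoch: Optional[int] = None

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        bad = sorted({s for s in stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stage labels {bad}; expected one of {STAGES}")
        lights_on = len(stages) if self.lights_on_epoch is None else self.lights_on_epoch
        object.__setattr__(self, "lights_on_epoch", lights_on)
        if not 0 <= self.lights_out_epoch < lights_on <= len(stages):
            raise ValueError(
                f"need 0 <= lights_out ({self.lights_out_epoch}) < lights_on "
                f"({lights_on}) <= n_epochs ({len(stages)})"
            )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def epoch_minutes(self) -> float:
        return self.epoch_seconds / 60.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_index": np.arange(len(self)), "stage": list(self.stages)})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "Hypnogram":
        df = df.sort_values("epoch_index")
        return cls(stages=tuple(df["stage"]), **kwargs)


@dataclass(frozen=True)
class LegMovement:
    epoch_index: int
    with_arousal: bool = False
    is_plms: bool = False


@dataclass(frozen=True)
class RespiratoryEvent:
    """Apnea or hypopnea; ``is_apnea`` separates apneas for the apnea index."""

    epoch_index: int
    is_apnea: bool = True


@dataclass
class EventAnnotations:
    """Scored events, indexed by 30-s epoch."""

    arousals: Sequence[int] = field(default_factory=list)
    movements: Sequence[int] = field(default_factory=list)
    leg_movements: Sequence[LegMovement] = field(default_factory=list)
    respiratory_events: Sequence[RespiratoryEvent] = field(default_factory=list)

    def validate(self, n_epochs: int) -> None:
        idx = (
            list(self.arousals)
            + list(self.movements)
            + [e.epoch_index for e in self.leg_movements]
            + [e.epoch_index for e in self.respiratory_events]
        )
        bad = [i for i in idx if not 0 <= i < n_epochs]
        if bad:
            raise IndexError(f"event epoch indices out of range [0, {n_epochs}): {sorted(set(bad))}")


@dataclass
class SleepMetrics:
    """One night's continuity, architecture and event-index variables."""

    tst_min: float
    sleep_efficiency_pct: float
    sol_min: float
    spt_min: float
    waso_min: float
    n_awakenings: int
    arousal_index_per_h: float
    pct_spt_n1: float
    pct_spt_n2: float
    pct_spt_sws: float
    pct_spt_rem: float
    leg_movements: int
    leg_movements_arousal: int
    plms: int
    plms_arousal: int
    plms_index: float
    plms_arousal_index: float
    ahi: float
    apnea_index: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def sleep_onset(h: Hypnogram) -> Optional[int]:
    """Index of the first N2 epoch at or after lights out; None if absent."""
    for i in range(h.lights_out_epoch, h.lights_on_epoch):
        if h.stages[i] == "N2":
            return i
    return None


class MetricsUndefinedError(ValueError):
    """Raised when a night has no sleep onset (no N2 epoch in bed)."""


def _wake_runs(stages: Sequence[str], start: int, stop: int) -> int:
    """Number of maximal contiguous wake runs in stages[start:stop]."""
    runs = 0
    in_run = False
    for i in range(start, stop):
        if stages[i] == "W":
            if not in_run:
                runs += 1
                in_run = True
        else:
            in_run = False
    return runs


def compute_sleep_metrics(h: Hypnogram, annotations: EventAnnotations | None = None) -> SleepMetrics:
    """Derive all continuity, architecture and event-index variables of a night.

    Raises
    ------
    MetricsUndefinedError
        If the night contains no N2 epoch between lights out and lights on
        (sleep onset — first epoch of stage 2 — is undefined).
    """
    annotations = annotations or EventAnnotations()
    annotations.validate(len(h))

    onset = sleep_onset(h)
    if onset is None:
        raise MetricsUndefinedError(
            "no stage-N2 epoch between lights out and lights on: "
            "sleep onset (first epoch of stage 2) is undefined"
        )
    epm = h.epoch_minutes
    lo, hi = h.lights_out_epoch, h.lights_on_epoch
    in_bed = list(h.stages[lo:hi])

    # TST counts all non-wake epochs in bed (pre-onset N1 included, rare with
    # onset defined by N2); final awakening = end of the last non-wake epoch.
    tst_min = sum(s != "W" for s in in_bed) * epm
    last_sleep = max(i for i in range(lo, hi) if h.stages[i] != "W")
    spt_min = (last_sleep - onset + 1) * epm
    waso_min = spt_min - tst_min  # WASO defined as SPT - TST, exact by construction
    tib_min = (hi - lo) * epm
    sol_min = (onset - lo) * epm
    se_pct = 100.0 * tst_min / tib_min

    n_awak = _wake_runs(h.stages, onset, last_sleep + 1)

    def pct(stage: str) -> float:
        n = sum(h.stages[i] == stage for i in range(onset, last_sleep + 1))
        return 100.0 * n * epm / spt_min

    tst_h = tst_min / 60.0

    def per_hour(count: int) -> float:
        return count / tst_h if tst_h > 0 else float("nan")

    lm = list(annotations.leg_movements)
    resp = list(annotations.respiratory_events)
    n_lm = len(lm)
    n_lm_ar = sum(e.with_arousal for e in lm)
    n_plms = sum(e.is_plms for e in lm)
    n_plms_ar = sum(e.is_plms and e.with_arousal for e in lm)
    n_resp = len(resp)
    n_apnea = sum(e.is_apnea for e in resp)

    return SleepMetrics(
        tst_min=tst_min,
        sleep_efficiency_pct=se_pct,
        sol_min=sol_min,
        spt_min=spt_min,
        waso_min=waso_min,
        n_awakenings=n_awak,
        arousal_index_per_h=per_hour(len(annotations.arousals)),
        pct_spt_n1=pct("N1"),
        pct_spt_n2=pct("N2"),
        pct_spt_sws=pct("SWS"),
        pct_spt_rem=pct("REM"),
        leg_movements=n_lm,
        leg_movements_arousal=n_lm_ar,
        plms=n_plms,
        plms_arousal=n_plms_ar,
        plms_index=per_hour(n_plms),
        plms_arousal_index=per_hour(n_plms_ar),
        ahi=per_hour(n_resp),
        apnea_index=per_hour(n_apnea),
    )


def eligibility_screen(m: SleepMetrics, limit_per_h: float = 5.0) -> tuple[bool, list[str]]:
    """Good-sleeper screen: fail on PLMS-arousal index or apnea index > 5.0/h.

    The boundary is inclusive: exactly 5.0/h passes.
    Returns (passed, reasons-for-failure).
    """
    reasons: list[str] = []
    if m.plms_arousal_index > limit_per_h:
        reasons.append(
            f"PLMS arousal index {m.plms_arousal_index:.2f}/h exceeds {limit_per_h}/h"
        )
    if m.apnea_index > limit_per_h:
        reasons.append(f"sleep apnea index {m.apnea_index:.2f}/h exceeds {limit_per_h}/h")
    return (not reasons, reasons)
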