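"""Classic per-patient BP-variability parameters over 24-h and day/night windows.

These are the conventional cross-sectional descriptors of a monitored BP
course: mean, max, min, range, sample SD, and SV (successive variation, the
root-mean-square of consecutive-reading differences), plus the two
single-time-point values used clinically (admission and immediately after the
1-h alteplase infusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import BPSeries

__all__ = [
    "BPSummary",
    "ClockContext",
    "summary_parameters",
    "day_night_masks",
    "point_values",
    "summarize_patients",
]


@dataclass(frozen=True)
class BPSummary:
    window: str  # "h24", "daytime" or "nighttime"
    mean: float
    max: float
    min: float
    range: float
    sd: float
    sv: float


@dataclass(frozen=True)
class ClockContext:
    """Clock-time anchoring of the monitoring window.

    ``onset_clock_time`` is the infusion start as "HH:MM"; readings whose
    clock time falls in ``[day_start, day_end)`` count as daytime.
    """

    onset_clock_time: str = "08:00"
    day_start: float = 6.0
    day_end: float = 22.0

    def __post_init__(self):
        span = (self.day_end - self.day_start) % 24.0
        if span == 0:
            raise ValueError("day window must be non-empty and shorter than 24 h")

    @property
    def onset_hours(self) -> float:
        hh, mm = self.onset_clock_time.split(":")
        return int(hh) + int(mm) / 60.0


def _parse_window(clock, start, end):
    """Half-open membership of clock hours in [start, end), wrapping midnight."""
    if start <= end:
        return (clock >= start) & (clock < end)
    return (clock >= start) | (clock < end)


def summary_parameters(series: BPSeries, mask=None, window="h24", sv_cv=False) -> BPSummary:
    """BP parameters over the readings selected by ``mask`` (default: all).

    SD uses divisor n-1; SV is sqrt(sum of squared successive differences /
    (m-1)) over the m selected readings in time order.  With ``sv_cv`` the SV
    is normalised by the window mean (dimensionless coefficient form).
    Requires >= 2 selected readings (SD/SV are undefined for one).
    """
    x = series.values if mask is None else series.values[np.asarray(mask)]
    if len(x) == 0:
        raise ValueError("mask selects no observations")
    if len(x) < 2:
        raise ValueError("SD and SV need at least 2 observations")
    d = np.diff(x)
    sv = float(np.sqrt(np.mean(d * d)))
    mean = float(np.mean(x))
    if sv_cv:
        sv = sv / mean
    return BPSummary(
        window=window,
        mean=mean,
        max=float(np.max(x)),
        min=float(np.min(x)),
        range=float(np.max(x) - np.min(x)),
        sd=float(np.std(x, ddof=1)),
        sv=sv,
    )


def day_night_masks(series: BPSeries, ctx: ClockContext):
    """Boolean (day, night) masks partitioning the series by clock time."""
    clock = (ctx.onset_hours + series.times) % 24.0
    day = _parse_window(clock, ctx.day_start % 24.0, ctx.day_end % 24.0)
    return day, ~day


def point_values(series: BPSeries, post_time=1.0) -> dict:
    """Admission reading and the reading nearest the end of the infusion.

    Admission is the earliest reading; ``post_thrombolysis`` the reading at
    the grid point nearest ``post_time`` (1 h = end of the alteplase
    infusion), ties resolved toward the earlier time.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    k = int(np.argmin(np.abs(series.times - post_time)))  # argmin: first minimum = earlier
    return {
        "admission": float(series.values[0]),
        "post_thrombolysis": float(series.values[k]),
    }


def summarize_patients(series_list, ctx: ClockContext | None = None, sv_cv=False) -> pd.DataFrame:
    """Per-patient parameter table over h24 / daytime / nighttime windows.

    One row per (patient, channel, window); single-point values are repeated
    on each row for convenience.  Windows with fewer than 2 readings are
    skipped (their statistics are undefined).
    """
    ctx = ctx or ClockContext()
    rows = []
    for s in series_list:
        pts = point_values(s)
        day, night = day_night_masks(s, ctx)
        for window, mask in (("h24", None), ("daytime", day), ("nighttime", night)):
            if mask is not None and mask.sum() < 2:
                continue
            sm = summary_parameters(s, mask, window=window, sv_cv=sv_cv)
            rows.append({
                "patient_id": s.patient_id, "channel": s.channel, "window": window,
                "mean": sm.mean, "max": sm.max, "min": sm.min, "range": sm.range,
                "sd": sm.sd, "sv": sm.sv, **pts,
            })
    return pd.DataFrame(rows)
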