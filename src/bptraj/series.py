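"""Core longitudinal containers: one patient's timed BP readings and censoring bounds."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

VALID_CHANNELS = ("SBP", "DBP")


@dataclass(frozen=True)
class BPSeries:
    """A single patient's blood-pressure readings for one channel.

    Times are hours since the start of the alteplase infusion, restricted to
    the 24-h monitoring window; values are in mmHg.
    """

    patient_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}")
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-d and the same length")
        if len(t) and (np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing")
        if len(t) and (t[0] < 0 or t[-1] > 24):
            raise ValueError("times must lie in [0, 24] hours")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("values must be finite and positive (mmHg)")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CensoringBounds:
    """Scale bounds for the censored-normal outcome distribution.

    Readings at or below ``lower`` / at or above ``upper`` contribute
    cumulative rather than density mass.  The defaults (infinite) disable
    censoring, which is appropriate for bedside BP telemetry that never sits
    on an instrument bound.
    """

    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("lower bound must be strictly below upper bound")

    @property
    def active(self) -> bool:
        return math.isfinite(self.lower) or math.isfinite(self.upper)
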