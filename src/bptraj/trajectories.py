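"""Polynomial trajectory shapes and the published 24-h BP group trajectories.

Each latent group's mean BP course over the 24 h after thrombolysis start is a
polynomial in time (hours).  The published fits describe five systolic and
four diastolic groups; their coefficients, descriptive labels and membership
proportions are shipped here so simulated cohorts reproduce that structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrajectoryShape",
    "evaluate_trajectory",
    "SBP_GROUPS",
    "DBP_GROUPS",
    "group_table",
]


@dataclass(frozen=True)
class TrajectoryShape:
    """Polynomial mean trajectory, coefficients intercept-first.

    ``coefficients[m]`` multiplies t**m, so units run mmHg, mmHg/h, mmHg/h², …
    Degree at most 4: the published group shapes are cubic or quartic.
    """

    coefficients: tuple

    def __post_init__(self):
        c = tuple(float(x) for x in self.coefficients)
        object.__setattr__(self, "coefficients", c)
        if not 1 <= len(c) <= 5:
            raise ValueError("polynomial degree must be between 0 and 4")
        if not all(np.isfinite(c)):
            raise ValueError("coefficients must be finite")

    @property
    def order(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, t):
        return evaluate_trajectory(self, t)


def evaluate_trajectory(shape: TrajectoryShape, t):
    """Evaluate the group mean trajectory at time(s) ``t`` (hours) -> mmHg."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    # Horner, intercept-first coefficients.
    out = np.zeros_like(t, dtype=float)
    for c in reversed(shape.coefficients):
        out = out * t + c
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupSpec:
    """One published trajectory group: label, shape, membership share."""

    label: str
    shape: TrajectoryShape
    proportion: float


# Published systolic groups (ascending BP level).  Proportions are the
# printed percentages / 100 and sum to 1 exactly.
SBP_GROUPS = (
    GroupSpec("slow drop-low", TrajectoryShape((115.677, -4.632, 0.690, -0.038, 0.0007)), 0.062),
    GroupSpec("rapid drop-low", TrajectoryShape((136.173, -5.822, 0.749, -0.039, 0.0007)), 0.218),
    GroupSpec("rapid drop-medium", TrajectoryShape((151.043, -5.849, 0.701, -0.033, 0.0006)), 0.348),
    GroupSpec("rapid drop-high", TrajectoryShape((165.549, -3.639, 0.232, -0.004)), 0.240),
    GroupSpec(
        "continuous fluctuation-very high",
        TrajectoryShape((174.543, -2.773, 0.223, -0.005)),
        0.132,
    ),
)

# Published diastolic groups.
DBP_GROUPS = (
    GroupSpec("rapid drop-low", TrajectoryShape((72.943, -3.199, 0.379, -0.019, 0.0004)), 0.193),
    GroupSpec("slow drop-medium", TrajectoryShape((80.997, -2.759, 0.326, -0.015, 0.0003)), 0.408),
    GroupSpec("rapid drop-high", TrajectoryShape((92.696, -2.545, 0.173, -0.003)), 0.319),
    GroupSpec(
        "continuous fluctuation-very high",
        TrajectoryShape((103.607, -4.175, 0.601, -0.031, 0.0005)),
        0.080,
    ),
)

PUBLISHED_GROUPS = {"SBP": SBP_GROUPS, "DBP": DBP_GROUPS}


def group_table(channel: str):
    """Shapes and proportions for one channel as (list of shapes, array of π)."""
    groups = PUBLISHED_GROUPS[channel]
    return [g.shape for g in groups], np.array([g.proportion for g in groups])
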