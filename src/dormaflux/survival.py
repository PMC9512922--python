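"""Caliper volumes, recurrence calling, and recurrence-free survival.

Tumor burden is tracked by caliper as V = L * W^2 / 2 (width = smallest
axis).  Day 0 is dox withdrawal; a tumor is considered recurrent after two
consecutive increasing caliper measurements that climb clear of the dormancy
plateau.  Recurrence-free survival (RFS) is summarized with the
Kaplan–Meier product-limit estimator and compared between arms with the
two-group log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank_test

__all__ = [
    "VolumeTrajectory",
    "RecurrenceCall",
    "KMEstimate",
    "tumor_volume",
    "call_recurrence",
    "km_estimate",
    "logrank_test",
    "percent_increase_rfs",
    "call_cohort",
]


def tumor_volume(length: float, width: float) -> float:
    """V = L * W^2 / 2 in mm^3, canonicalizing so width is the smaller axis."""
    length = float(length)
    width = float(width)
    if length <= 0 or width <= 0:
        raise ValueError("caliper axes must be positive")
    if width > length:
        length, width = width, length
    return length * width**2 / 2.0


@dataclass
class VolumeTrajectory:
    """Per-mouse caliper series, days relative to dox withdrawal (day 0)."""

    mouse_id: str
    arm: str
    days: np.ndarray
    lengths: np.ndarray
    widths: np.ndarray
    true_recurrence_day: float | None = None  # generator ground truth only

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if not (len(self.days) == len(self.lengths) == len(self.widths)):
            raise ValueError("days/lengths/widths must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("measurement days must be strictly increasing")
        if np.any(self.lengths <= 0) or np.any(self.widths <= 0):
            raise ValueError("caliper axes must be positive")
        # canonicalize: width is the smallest axis
        swap = self.widths > self.lengths
        if np.any(swap):
            l, w = self.lengths.copy(), self.widths.copy()
            self.lengths = np.where(swap, w, l)
            self.widths = np.where(swap, l, w)

    @property
    def volumes(self) -> np.ndarray:
        return self.lengths * self.widths**2 / 2.0

    @property
    def normalized_volumes(self) -> np.ndarray:
        """Volumes normalized to the day-0 measurement."""
        v = self.volumes
        at0 = np.flatnonzero(self.days >= 0)
        if at0.size == 0:
            raise ValueError("trajectory has no measurement at or after day 0")
        return v / v[at0[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": self.mouse_id,
                "arm": self.arm,
                "day": self.days,
                "length_mm": self.lengths,
                "width_mm": self.widths,
                "volume_mm3": self.volumes,
            }
        )


@dataclass(frozen=True)
class RecurrenceCall:
    """Outcome of the recurrence rule for one mouse."""

    mouse_id: str
    time: float  # recurrence day, or censoring day when event is False
    event: bool
    baseline_volume: float | None = None


def call_recurrence(
    traj: VolumeTrajectory,
    *,
    delta: float = 0.10,
    regression_threshold: float = 0.5,
    min_baseline_points: int = 3,
) -> RecurrenceCall:
    """Call recurrence from two consecutive increasing measurements that rise
    clear of the dormancy plateau.

    The post-regression window opens once volume first falls below
    ``regression_threshold`` of the day-0 volume.  Scanning forward, the
    dormancy baseline before each candidate pair is the median of the
    post-regression measurements seen so far (at least
    ``min_baseline_points`` of them).  Recurrence is called at the first pair
    of strictly increasing measurements that both exceed the baseline by the
    relative margin ``delta`` and that initiate a sustained escape — no
    later measurement falls back below that threshold (calling is
    retrospective, so the full trajectory is available to adjudicate; a
    chance up-tick of caliper noise during dormancy relaxes back, whereas
    exponential regrowth does not).  The recurrence day is the first day of
    the pair.  With no qualifying pair the mouse is censored at its last
    measurement day.
    """
    post = traj.days >= 0
    days = traj.days[post]
    volumes = traj.volumes[post]
    if len(days) < 3:
        raise ValueError("trajectory needs >= 3 post-withdrawal measurements")
    v0 = volumes[0]
    below = np.flatnonzero(volumes < regression_threshold * v0)
    censored = RecurrenceCall(traj.mouse_id, float(days[-1]), False)
    if below.size == 0:
        return censored  # never regressed: no dormancy to recur from
    start = int(below[0])
    for i in range(start + 2, len(days)):
        window = volumes[start : i - 1]
        if window.size < min_baseline_points:
            continue
        baseline = float(np.median(window))
        threshold = baseline * (1.0 + delta)
        if (
            volumes[i - 1] > volumes[i - 2]
            and volumes[i] > volumes[i - 1]
            and volumes[i - 1] > threshold
            and volumes[i] > threshold
            and np.all(volumes[i + 1 :] > threshold)
        ):
            return RecurrenceCall(
                traj.mouse_id, float(days[i - 1]), True, baseline_volume=baseline
            )
    return censored


def call_cohort(
    trajectories: list[VolumeTrajectory], *, delta: float = 0.10
) -> pd.DataFrame:
    """Apply the recurrence rule to a cohort; one row per mouse."""
    calls = [call_recurrence(t, delta=delta) for t in trajectories]
    return pd.DataFrame(
        {
            "mouse_id": [c.mouse_id for c in calls],
            "arm": [t.arm for t in trajectories],
            "time": [c.time for c in calls],
            "event": [c.event for c in calls],
        }
    )


@dataclass
class KMEstimate:
    """Kaplan–Meier product-limit estimate of recurrence-free survival."""

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    n_at_risk: np.ndarray
    median_rfs: float  # nan when the curve never reaches 0.5

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median_rfs)


def km_estimate(times, events) -> KMEstimate:
    """Product-limit estimator; median = first time S(t) <= 0.5."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_["KM_estimate"]
    median = float(kmf.median_survival_time_)  # inf when S never reaches 0.5
    return KMEstimate(
        event_times=surv.index.to_numpy(dtype=float),
        survival_probabilities=surv.to_numpy(dtype=float),
        n_at_risk=kmf.event_table["at_risk"].to_numpy(),
        median_rfs=median if math.isfinite(median) else float("nan"),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p from chi2_1)."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be nonempty")
    if not events_a.any() and not events_b.any():
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    result = _ll_logrank_test(times_a, times_b, events_a, events_b)
    return float(result.test_statistic), float(result.p_value)


def percent_increase_rfs(median_ref: float, median_alt: float) -> float:
    """Percent increase in median RFS of the alternative arm over reference."""
    if not (math.isfinite(median_ref) and math.isfinite(median_alt)):
        raise ValueError("both medians must be defined (finite)")
    if median_ref <= 0:
        raise ValueError("reference median must be > 0")
    return 100.0 * (median_alt - median_ref) / median_ref
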