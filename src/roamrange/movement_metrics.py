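"""Per-dog movement outcomes: distance travelled and household occupancy.

Distance is the sum of planar step lengths of the cleaned track; daily
distance rescales the total to a 24 h day using the recording span.
Household occupancy attributes each inter-fix interval to the location of
its earlier fix (last observation carried forward): under motion-triggered
logging, gaps are predominantly rest at the last seen location, so LOCF is
the faithful time attribution.  A fix-count-weighted variant is provided
for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import SampledTrack

logger = logging.getLogger("roamrange")


@dataclass(frozen=True)
class HouseholdArea:
    """Circular household compound: centre in planar metres, radius 20 m."""

    center: tuple[float, float]
    radius_m: float = 20.0

    def __post_init__(self) -> None:
        if not self.radius_m > 0:
            raise ValueError("household radius must be positive")


@dataclass
class MovementSummary:
    """The per-dog outcome vector feeding the risk-factor analysis."""

    dog_id: str
    daily_distance_km: float = np.nan
    total_distance_km: float = np.nan
    core_hr_ha: float = np.nan       # filled by the home-range module
    extended_hr_ha: float = np.nan   # filled by the home-range module
    pct_time_household: float = np.nan
    recording_hours: float = np.nan
    fixes_per_hour: float = np.nan
    extras: dict = field(default_factory=dict)


def total_and_daily_distance(track: SampledTrack) -> tuple[float, float]:
    """(total km, km/day) from planar step lengths of a cleaned track.

    daily = total * 24 / recording_hours; robust to partial first/last
    days.  A zero recording span leaves daily undefined (NaN, logged).
    """
    if track.n_fixes < 2:
        raise ValueError("need at least 2 fixes for distances")
    steps = np.hypot(*np.diff(track.xy(), axis=0).T)
    total_km = float(steps.sum()) / 1000.0
    hours = track.recording_hours
    if hours <= 0:
        logger.warning("%s: zero recording span; daily distance undefined", track.dog_id)
        return total_km, float("nan")
    return total_km, total_km * 24.0 / hours


def daily_distance_per_calendar_day(track: SampledTrack) -> "np.ndarray":
    """Optional per-calendar-day totals (km), for sensitivity analysis."""
    if track.n_fixes < 2:
        raise ValueError("need at least 2 fixes for distances")
    steps = np.hypot(*np.diff(track.xy(), axis=0).T) / 1000.0
    days = track.fixes["timestamp"].dt.date.to_numpy()
    # attribute each step to the calendar day of its earlier fix
    import pandas as pd

    return pd.Series(steps).groupby(days[:-1]).sum().to_numpy()


def household_occupancy(
    track: SampledTrack,
    area: HouseholdArea,
    weighting: str = "time",
    max_gap_s: float | None = None,
) -> float:
    """Percent of the recording period spent inside the household area.

    ``weighting="time"`` (default) sums the durations of inter-fix
    intervals whose *earlier* fix lies within the radius, divided by the
    recording span.  ``weighting="count"`` uses the fraction of fixes
    inside.  ``max_gap_s`` optionally caps the duration credited to any
    single interval (gaps are rest, hence informative; the cap exists only
    for sensitivity analysis).
    """
    if track.n_fixes < 2:
        raise ValueError("need at least 2 fixes for occupancy")
    xy = track.xy()
    inside = np.hypot(xy[:, 0] - area.center[0], xy[:, 1] - area.center[1]) <= area.radius_m
    if weighting == "count":
        return float(inside.mean()) * 100.0
    if weighting != "time":
        raise ValueError("weighting must be 'time' or 'count'")
    gaps = np.diff(track.times_s())
    if max_gap_s is not None:
        gaps = np.minimum(gaps, max_gap_s)
    span = gaps.sum()
    if span <= 0:
        raise ValueError("zero recording span")
    return float(gaps[inside[:-1]].sum() / span) * 100.0


def summarize_movement(
    track: SampledTrack,
    household: HouseholdArea | None = None,
    fixes_per_hour: float = np.nan,
) -> MovementSummary:
    """Assemble distances + occupancy for one cleaned, projected track."""
    total_km, daily_km = total_and_daily_distance(track)
    if household is None:
        if track.household_xy is None:
            raise ValueError(f"{track.dog_id}: no household location available")
        household = HouseholdArea(center=track.household_xy)
    pct = household_occupancy(track, household)
    return MovementSummary(
        dog_id=track.dog_id,
        daily_distance_km=daily_km,
        total_distance_km=total_km,
        pct_time_household=pct,
        recording_hours=track.recording_hours,
        fixes_per_hour=fixes_per_hour,
    )
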