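"""Fix- and dog-level exclusion rules and sampling summaries.

Two cleaning rules are applied before any movement analysis:

* step-speed filter — the average speed between successive fixes is
  computed on the planar track; whenever a step exceeds the threshold
  (default 20 km/h, a speed a village dog will not sustain for a whole
  minute) the *later* fix of the pair is dropped and speeds recomputed,
  iterating to a fixed point;
* short-deployment exclusion — dogs whose recording span (last fix minus
  first fix) is below a minimum (default 24 h) are excluded from the
  cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory_io import SampledTrack

logger = logging.getLogger("roamrange")

KMH_PER_MS = 3.6


@dataclass(frozen=True)
class CleaningParams:
    speed_threshold_kmh: float = 20.0
    min_recording_hours: float = 24.0

    def __post_init__(self) -> None:
        if not (self.speed_threshold_kmh > 0 and self.min_recording_hours > 0):
            raise ValueError("cleaning thresholds must be positive")


@dataclass(frozen=True)
class SamplingSummary:
    """Per-dog recording effort after cleaning."""

    dog_id: str
    recording_hours: float
    fixes_per_hour: float  # NaN for single-fix tracks (undefined)
    n_fixes_raw: int
    n_fixes_clean: int


def compute_speeds(track: SampledTrack) -> np.ndarray:
    """Average travel speed (km/h) for every step between successive fixes.

    Zero-duration steps (possible only if deduplication was bypassed) are
    flagged as NaN rather than infinity.
    """
    if track.n_fixes < 2:
        raise ValueError("need at least 2 fixes to compute speeds")
    xy = track.xy()
    dt = np.diff(track.times_s())
    dist = np.hypot(*np.diff(xy, axis=0).T)
    with np.errstate(divide="ignore", invalid="ignore"):
        speeds = np.where(dt > 0, dist / np.where(dt > 0, dt, 1.0) * KMH_PER_MS, np.nan)
    return speeds


def filter_by_speed(
    track: SampledTrack, params: CleaningParams = CleaningParams()
) -> tuple[SampledTrack, int]:
    """Drop fixes implying impossible speeds; return the clean track and count.

    The later fix of any step whose speed exceeds the threshold is removed
    (the jump is treated as the error) and speeds are recomputed, until no
    step exceeds the threshold.  Each pass removes at least one fix, so the
    procedure terminates.  Surviving fixes are untouched.  If the track
    would fall below 2 fixes it is returned as-is with a warning.
    """
    out = track.copy()
    n_removed = 0
    while out.n_fixes >= 2:
        speeds = compute_speeds(out)
        over = np.flatnonzero(speeds > params.speed_threshold_kmh)
        if over.size == 0:
            break
        # removing an index shifts later ones; drop the first offender per
        # pass and recompute -- simple and exactly matches the iterative rule
        drop = int(over[0]) + 1  # the LATER fix of the offending step
        logger.debug(
            "%s: removing fix %d (step speed %.1f km/h > %.1f)",
            out.dog_id, drop, speeds[over[0]], params.speed_threshold_kmh,
        )
        out.fixes = out.fixes.drop(index=out.fixes.index[drop]).reset_index(drop=True)
        n_removed += 1
    if out.n_fixes < 2 and track.n_fixes >= 2:
        logger.warning("%s: speed filter would leave <2 fixes; keeping as-is", track.dog_id)
    return out, n_removed


def exclude_short_recordings(
    tracks: list[SampledTrack], params: CleaningParams = CleaningParams()
) -> tuple[list[SampledTrack], list[str]]:
    """Split a cohort into kept tracks and excluded dog ids.

    A dog is excluded when its recording span is strictly less than the
    minimum (a span of exactly 24.0 h is kept).
    """
    kept, excluded = [], []
    for t in tracks:
        if t.recording_hours < params.min_recording_hours:
            excluded.append(t.dog_id)
        else:
            kept.append(t)
    if excluded:
        logger.info("excluded %d dogs with <%.0f h of data: %s",
                    len(excluded), params.min_recording_hours, excluded)
    return kept, excluded


def summarize_sampling(track: SampledTrack, n_fixes_raw: int | None = None) -> SamplingSummary:
    """Recording hours and fixes/hour for a cleaned track.

    Single-fix tracks have zero span and an undefined rate (NaN).
    """
    hours = track.recording_hours
    if track.n_fixes < 2 or hours <= 0:
        logger.warning("%s: degenerate track (%d fixes, %.2f h); rate undefined",
                       track.dog_id, track.n_fixes, hours)
        rate = float("nan")
        hours = 0.0 if track.n_fixes < 2 else hours
    else:
        rate = track.n_fixes / hours
    return SamplingSummary(
        dog_id=track.dog_id,
        recording_hours=hours,
        fixes_per_hour=rate,
        n_fixes_raw=track.n_fixes if n_fixes_raw is None else n_fixes_raw,
        n_fixes_clean=track.n_fixes,
    )


def clean_track(
    track: SampledTrack, params: CleaningParams = CleaningParams()
) -> tuple[SampledTrack, SamplingSummary]:
    """Speed-filter one projected track and summarise its sampling effort."""
    n_raw = track.n_fixes
    clean, n_removed = filter_by_speed(track, params)
    summary = summarize_sampling(clean, n_fixes_raw=n_raw)
    logger.info("%s: %d raw fixes, %d removed by speed filter, %.1f fixes/h",
                track.dog_id, n_raw, n_removed, summary.fixes_per_hour)
    return clean, summary
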