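"""Synthetic free-roaming-dog GPS tracks with known ground truth.

The generator emulates the field deployment: a collar programmed to
record one fix per minute *while the dog is moving*, worn for about five
days by a home-anchored dog that makes excursions to a few attraction
sites (other compounds, fields, rubbish dumps).

Movement model (two behavioural states, switching by exponential clocks):

* **rest** — the dog is stationary at wherever it stopped;
* **travel** — the dog heads for a target (its household, or an
  attraction site drawn by weight) following a speed-clipped
  Ornstein-Uhlenbeck process: drift ``min(beta * d, v_cruise)`` toward
  the target plus isotropic diffusion.  Far from the target this is a
  straight trot at cruise speed; near it, OU jitter around the site.

Fixes are emitted on a one-minute clock only when the displacement over
the preceding minute implies a rate above the logger's motion threshold,
then perturbed by Gaussian GPS noise — so rest produces informative gaps
and the recorded rate lands near the ~21 fixes/hour seen on real
collars.  Ground truth (household-time fraction, path length at the
logger's nominal resolution, per-site visit fractions) is computed from
the dense noise-free path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .trajectory_io import (
    AGE_CLASSES, SEX_STATUSES, TIME_OUTSIDE,
    DogMetadata, SampledTrack, UTMZone, utm_forward, utm_inverse,
    write_track_csv,
)

logger = logging.getLogger("roamrange")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one simulated deployment.

    Coordinates are planar metres relative to the household.  Defaults
    are tuned to the study conditions: ~5-day deployments, a median
    around 20 recorded fixes/hour, daily distances of order 15 km and
    roughly a third of the time spent within 20 m of the household.
    """

    household_center: tuple[float, float] = (0.0, 0.0)
    #: [( (x, y), weight ), ...] excursion destinations
    attraction_sites: tuple = ()
    #: relative weight of the household as an excursion target
    home_target_weight: float = 3.0
    #: mean-reversion strength beta of the travel OU, 1/s (inf = pinned)
    home_attraction_rate: float = 0.01
    #: drift speed cap while travelling, m/s
    cruise_speed: float = 2.0
    #: true diffusion of the travel state, m^2/s
    diffusion_true: float = 0.4
    deployment_hours: float = 120.0
    fix_interval_s: float = 60.0
    #: logger motion gate: no fix below this displacement rate, m/s
    move_speed_threshold: float = 0.05
    gps_noise_sd: float = 2.5
    outlier_rate: float = 0.0
    outlier_jump: float = 1000.0
    #: exponential bout means, s
    mean_rest_s: float = 1400.0
    mean_travel_s: float = 700.0
    #: dense simulation step, s (must divide fix_interval_s)
    sim_dt: float = 5.0
    #: radius defining "at the household" / "at a site", m
    household_radius: float = 20.0
    site_radius: float = 20.0
    #: geographic anchor (WGS84) of the planar origin, and the UTM zone
    ref_lonlat: tuple[float, float] = (34.09, 0.46)
    zone: UTMZone = field(default_factory=UTMZone)
    start_time: str = "2019-06-10 06:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        finite_fields = {
            "cruise_speed": self.cruise_speed,
            "diffusion_true": self.diffusion_true,
            "deployment_hours": self.deployment_hours,
            "fix_interval_s": self.fix_interval_s,
            "move_speed_threshold": self.move_speed_threshold,
            "gps_noise_sd": self.gps_noise_sd,
            "outlier_jump": self.outlier_jump,
            "mean_rest_s": self.mean_rest_s,
            "mean_travel_s": self.mean_travel_s,
            "sim_dt": self.sim_dt,
        }
        for name, val in finite_fields.items():
            if not math.isfinite(val):
                raise ValueError(f"SimConfig.{name} must be finite, got {val}")
        if self.deployment_hours <= 0 or self.fix_interval_s <= 0:
            raise ValueError("deployment_hours and fix_interval_s must be positive")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.home_attraction_rate < 0 or math.isnan(self.home_attraction_rate):
            raise ValueError("home_attraction_rate must be >= 0 (inf allowed)")
        if any(w < 0 for _, w in self.attraction_sites) or self.home_target_weight < 0:
            raise ValueError("target weights must be >= 0")
        if self.diffusion_true < 0:
            raise ValueError("diffusion_true must be >= 0")
        if abs(self.fix_interval_s / self.sim_dt - round(self.fix_interval_s / self.sim_dt)) > 1e-9:
            raise ValueError("sim_dt must divide fix_interval_s")


@dataclass(frozen=True)
class TruthSummary:
    """Ground truth from the dense noise-free path.

    ``true_total_path_m`` is the path length sampled at the logger's
    nominal fix interval: a diffusive path has no scale-free length, so
    truth and fix-based estimates are compared at matched temporal
    resolution.
    """

    true_fraction_at_household: float  # % of simulated time within radius
    true_total_path_m: float
    site_visit_fractions: tuple = ()   # % per attraction site, same order


# ---------------------------------------------------------------------------
# Dense-path simulation
# ---------------------------------------------------------------------------

def _travel_segment(x0, target, n, cfg: SimConfig, rng) -> np.ndarray:
    """n positions of the speed-clipped OU heading for ``target``."""
    target = np.asarray(target, dtype=float)
    if not math.isfinite(cfg.home_attraction_rate):
        return np.tile(target, (n, 1))  # infinitely strong pull: pinned
    dt = cfg.sim_dt
    beta, vmax = cfg.home_attraction_rate, cfg.cruise_speed
    noise = rng.standard_normal((n, 2)) * math.sqrt(2.0 * cfg.diffusion_true * dt)
    out = np.empty((n, 2))
    x = np.array(x0, dtype=float)
    for k in range(n):
        dvec = target - x
        dist = math.hypot(dvec[0], dvec[1])
        if dist > 0.0:
            step = min(beta * dist, vmax) * dt
            x = x + (min(step, dist) / dist) * dvec + noise[k]
        else:
            x = x + noise[k]
        out[k] = x
    return out


def _pick_target(cfg: SimConfig, rng) -> np.ndarray:
    weights = [cfg.home_target_weight] + [w for _, w in cfg.attraction_sites]
    total = float(sum(weights))
    if total <= 0:
        return np.asarray(cfg.household_center, dtype=float)
    i = rng.choice(len(weights), p=np.asarray(weights) / total)
    if i == 0:
        return np.asarray(cfg.household_center, dtype=float)
    return np.asarray(cfg.attraction_sites[i - 1][0], dtype=float)


def _simulate_dense_path(cfg: SimConfig, rng) -> np.ndarray:
    """(n_steps + 1, 2) noise-free positions at sim_dt resolution."""
    n_steps = int(round(cfg.deployment_hours * 3600.0 / cfg.sim_dt))
    path = np.empty((n_steps + 1, 2))
    path[0] = cfg.household_center
    k = 0
    resting = True  # collar goes on while the dog is at home, at rest
    while k < n_steps:
        mean = cfg.mean_rest_s if resting else cfg.mean_travel_s
        n_bout = max(1, int(round(rng.exponential(mean) / cfg.sim_dt)))
        n_bout = min(n_bout, n_steps - k)
        if resting:
            path[k + 1:k + 1 + n_bout] = path[k]
        else:
            target = _pick_target(cfg, rng)
            path[k + 1:k + 1 + n_bout] = _travel_segment(
                path[k], target, n_bout, cfg, rng
            )
        k += n_bout
        resting = not resting
    return path


def _truth_from_path(path: np.ndarray, cfg: SimConfig) -> TruthSummary:
    home = np.asarray(cfg.household_center)
    # left-endpoint time weighting over sim_dt intervals
    occ = path[:-1]
    d_home = np.hypot(occ[:, 0] - home[0], occ[:, 1] - home[1])
    frac_home = float((d_home <= cfg.household_radius).mean()) * 100.0
    site_fracs = []
    for (sx, sy), _w in cfg.attraction_sites:
        d = np.hypot(occ[:, 0] - sx, occ[:, 1] - sy)
        site_fracs.append(float((d <= cfg.site_radius).mean()) * 100.0)
    m = int(round(cfg.fix_interval_s / cfg.sim_dt))
    coarse = path[::m]
    total = float(np.hypot(*np.diff(coarse, axis=0).T).sum())
    return TruthSummary(
        true_fraction_at_household=frac_home,
        true_total_path_m=total,
        site_visit_fractions=tuple(site_fracs),
    )


def _emit_fixes(path: np.ndarray, cfg: SimConfig, rng) -> SampledTrack | None:
    """Motion-gated fix emission + GPS noise; None if nothing triggers."""
    m = int(round(cfg.fix_interval_s / cfg.sim_dt))
    fix_idx = np.arange(m, len(path), m)
    disp = np.hypot(*(path[fix_idx] - path[fix_idx - m]).T)
    emit = disp / cfg.fix_interval_s >= cfg.move_speed_threshold
    idx = fix_idx[emit]
    if idx.size == 0:
        logger.info("no fixes emitted (dog never exceeded the motion gate)")
        return None
    xy = path[idx] + rng.standard_normal((idx.size, 2)) * cfg.gps_noise_sd

    # the simulation's planar origin is anchored at ref_lonlat, so dogs of
    # one cohort (sharing a ref) keep their relative geometry
    e0, n0 = utm_forward(*cfg.ref_lonlat, cfg.zone)
    ex = float(e0) + xy[:, 0]
    ny = float(n0) + xy[:, 1]
    lon, lat = utm_inverse(ex, ny, cfg.zone)
    hh_xy = (float(e0) + cfg.household_center[0], float(n0) + cfg.household_center[1])
    hh_ll = utm_inverse(hh_xy[0], hh_xy[1], cfg.zone)
    start = pd.Timestamp(cfg.start_time, tz="Etc/GMT-3")
    ts = start + pd.to_timedelta(idx * cfg.sim_dt, unit="s")
    frame = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat, "x": ex, "y": ny})
    return SampledTrack(
        dog_id=f"sim{cfg.seed:05d}",
        fixes=frame,
        household_lonlat=(float(hh_ll[0]), float(hh_ll[1])),
        household_xy=hh_xy,
        zone=cfg.zone,
    )


def simulate_track(cfg: SimConfig) -> tuple[SampledTrack | None, TruthSummary]:
    """Simulate one deployment; identical seed => identical output.

    Returns ``(track, truth)``; ``track`` is ``None`` when the dog never
    moved fast enough to trigger a single fix.
    """
    rng = np.random.default_rng(cfg.seed)
    path = _simulate_dense_path(cfg, rng)
    truth = _truth_from_path(path, cfg)
    track = _emit_fixes(path, cfg, rng)
    return track, truth


def inject_outliers(
    track: SampledTrack, rate: float, jump: float, seed: int
) -> tuple[SampledTrack, int]:
    """Displace each fix independently by ``jump`` metres with prob ``rate``.

    Creates the spurious >20 km/h fixes the speed filter must remove.
    Displacement direction is uniform; geographic coordinates are kept
    consistent with the planar ones.  Returns (new track, count moved).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if jump <= 0:
        raise ValueError("jump must be positive")
    if track.n_fixes == 0:
        raise ValueError("cannot inject outliers into an empty track")
    rng = np.random.default_rng(seed)
    out = track.copy()
    hit = rng.random(out.n_fixes) < rate
    n_hit = int(hit.sum())
    if n_hit:
        theta = rng.uniform(0.0, 2.0 * math.pi, n_hit)
        x = out.fixes["x"].to_numpy(dtype=float)
        y = out.fixes["y"].to_numpy(dtype=float)
        x[hit] += jump * np.cos(theta)
        y[hit] += jump * np.sin(theta)
        out.fixes["x"] = x
        out.fixes["y"] = y
        lon, lat = utm_inverse(x[hit], y[hit], out.zone)
        out.fixes.loc[hit, "lon"] = lon
        out.fixes.loc[hit, "lat"] = lat
    return out, n_hit


# ---------------------------------------------------------------------------
# Cohort simulation (the study layout: 8 sites, 73 dogs)
# ---------------------------------------------------------------------------

#: dogs per site, matching the analysed cohort layout
DEFAULT_SITE_SIZES = (9, 9, 10, 9, 10, 8, 10, 8)

_AGE_P = (0.07, 0.77, 0.16)
_SEX_P = (0.31, 0.14, 0.48, 0.07)
_TIME_P = (0.64, 0.24, 0.12)


@dataclass
class SimulatedDog:
    config: SimConfig
    metadata: DogMetadata
    track: SampledTrack | None
    truth: TruthSummary


def simulate_cohort(
    seed: int = 0,
    site_sizes: tuple[int, ...] = DEFAULT_SITE_SIZES,
    deployment_hours: float | None = None,
    gps_noise_sd: float | None = None,
) -> list[SimulatedDog]:
    """Simulate a full study cohort with per-site shared attraction sites.

    Each site gets a village centre ~3 km from its neighbours, three
    communal attraction points (other compounds, a field, a dump) shared
    by its dogs, and households scattered within ~300 m of the centre.
    Dog-level behavioural parameters vary log-normally around the
    defaults; deployment lengths mimic the observed distribution (mostly
    4-6 days, a small fraction cut short).  Metadata categories are drawn
    with the cohort frequencies reported in the field study.
    """
    rng = np.random.default_rng(seed)
    dogs: list[SimulatedDog] = []
    base = SimConfig()
    for s, n_dogs in enumerate(site_sizes):
        site_name = f"site{s + 1}"
        cx = 3000.0 * (s % 4)
        cy = 3000.0 * (s // 4)
        n_attr = 3
        ang = rng.uniform(0, 2 * math.pi, n_attr)
        rad = rng.uniform(220.0, 420.0, n_attr)
        attr = tuple(
            ((cx + r * math.cos(a), cy + r * math.sin(a)), 1.0)
            for a, r in zip(ang, rad)
        )
        for d in range(n_dogs):
            house = (cx + rng.uniform(-300, 300), cy + rng.uniform(-300, 300))
            if deployment_hours is not None:
                hours = deployment_hours
            elif rng.random() < 0.14:
                hours = float(rng.uniform(25.0, 96.0))
            else:
                hours = float(rng.uniform(96.0, 152.0))
            cfg = SimConfig(
                household_center=house,
                attraction_sites=attr,
                cruise_speed=float(base.cruise_speed * rng.lognormal(0.0, 0.15)),
                diffusion_true=float(base.diffusion_true * rng.lognormal(0.0, 0.25)),
                mean_rest_s=float(base.mean_rest_s * rng.lognormal(0.0, 0.3)),
                mean_travel_s=float(base.mean_travel_s * rng.lognormal(0.0, 0.2)),
                deployment_hours=hours,
                gps_noise_sd=base.gps_noise_sd if gps_noise_sd is None else gps_noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
            md = DogMetadata(
                dog_id=f"dog_{site_name}_{d + 1:02d}",
                site=site_name,
                age_class=AGE_CLASSES[rng.choice(3, p=_AGE_P)],
                sex_status=SEX_STATUSES[rng.choice(4, p=_SEX_P)],
                reported_time_outside=TIME_OUTSIDE[rng.choice(3, p=_TIME_P)],
            )
            track, truth = simulate_track(cfg)
            if track is not None:
                track.dog_id = md.dog_id
            dogs.append(SimulatedDog(config=cfg, metadata=md, track=track, truth=truth))
    return dogs


# ---------------------------------------------------------------------------
# Analysis-table simulation (mixed-model calibration)
# ---------------------------------------------------------------------------

def simulate_analysis_table(
    seed: int,
    n_dogs: int = 73,
    n_sites: int = 8,
    beta_fixes: float = 0.0,
    sex_effects: tuple[float, float, float] = (0.0, 0.0, 0.0),
    age_effect: float = 0.0,
    icc: float = 0.0,
    resid_sd: float = 4.0,
    intercept: float = 13.0,
) -> pd.DataFrame:
    """Per-dog outcome table with a known site random effect.

    ``icc`` fixes the between-site share of variance
    (sigma_b^2 = icc / (1 - icc) * resid_sd^2).  Covariates mirror the
    questionnaire structure: dichotomised age, four-level sex/neuter
    status, and a continuous fixes/hour.  Used for coefficient- and
    ICC-recovery calibration of the mixed models.
    """
    rng = np.random.default_rng(seed)
    site = np.array([f"site{i % n_sites + 1}" for i in range(n_dogs)])
    sigma_b = math.sqrt(icc / (1.0 - icc)) * resid_sd if icc > 0 else 0.0
    site_eff = {f"site{i + 1}": rng.normal(0.0, sigma_b) for i in range(n_sites)}
    age_ge1 = (rng.random(n_dogs) < 0.93).astype(int)
    sex = rng.choice(4, size=n_dogs, p=_SEX_P)
    fixes = rng.uniform(5.0, 33.0, n_dogs)
    y = (
        intercept
        + age_effect * age_ge1
        + np.array([(0.0,) + tuple(sex_effects)])[0][sex]
        + beta_fixes * (fixes - fixes.mean())
        + np.array([site_eff[s] for s in site])
        + rng.normal(0.0, resid_sd, n_dogs)
    )
    return pd.DataFrame(
        {
            "dog_id": [f"dog{i:03d}" for i in range(n_dogs)],
            "site": site,
            "outcome": y,
            "age_ge1": age_ge1,
            "sex_status": np.array(SEX_STATUSES)[sex],
            "fixes_per_hour": fixes,
        }
    )


# ---------------------------------------------------------------------------
# File emission (logger-dialect CSV + truth JSON)
# ---------------------------------------------------------------------------

def write_truth_json(truth: TruthSummary, cfg: SimConfig, path) -> None:
    payload = {
        "truth": asdict(truth),
        "config": {
            k: v for k, v in asdict(cfg).items()
            if isinstance(v, (int, float, str, list, tuple))
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


def simulate_batch(out_dir, n_dogs: int = 5, seed: int = 0, **overrides) -> list[str]:
    """Write one (CSV, truth JSON) pair per simulated dog; return dog ids."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    ids = []
    for i in range(n_dogs):
        cfg = SimConfig(seed=int(rng.integers(2**31 - 1)), **overrides)
        track, truth = simulate_track(cfg)
        dog_id = f"dog{i + 1:03d}"
        if track is None:
            logger.warning("%s: zero fixes; truth JSON only", dog_id)
        else:
            track.dog_id = dog_id
            write_track_csv(track, os.path.join(out_dir, f"{dog_id}.csv"))
        write_truth_json(truth, cfg, os.path.join(out_dir, f"{dog_id}_truth.json"))
        ids.append(dog_id)
    return ids
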