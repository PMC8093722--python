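"""Reading logger CSV exports, metadata tables, and planar projection.

GPS collar exports arrive as one CSV per dog (index, ISO date-time,
latitude, longitude, elevation).  Tracks are held as a pandas DataFrame
wrapped in :class:`SampledTrack`, with WGS84 geographic coordinates and,
after :func:`project_to_planar`, UTM easting/northing in metres.

The projection is a WGS84 transverse Mercator (UTM) implemented with the
Krueger series in the conformal-latitude form to sixth order in the third
flattening, which is accurate to well below a millimetre over a UTM zone.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("roamrange")

# ---------------------------------------------------------------------------
# WGS84 / transverse Mercator
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

_N = _WGS84_F / (2.0 - _WGS84_F)
_E2 = _WGS84_F * (2.0 - _WGS84_F)          # first eccentricity squared
_ECC = math.sqrt(_E2)

# rectifying radius
_A_RECT = _WGS84_A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# forward series coefficients (Karney 2011, alpha_j to n^6)
_ALPHA = (
    _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
    - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
    13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440 + 281 * _N**5 / 630
    - 1983433 * _N**6 / 1935360,
    61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
    + 167603 * _N**6 / 181440,
    49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
    34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
    212378941 * _N**6 / 319334400,
)

# inverse series coefficients (beta_j to n^6)
_BETA = (
    _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
    - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
    _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440 + 46 * _N**5 / 105
    - 1118711 * _N**6 / 3870720,
    17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
    + 5569 * _N**6 / 90720,
    4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
    4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
    20648693 * _N**6 / 638668800,
)


@dataclass(frozen=True)
class UTMZone:
    """A UTM zone of the WGS84 ellipsoid (the study default is 36N)."""

    zone: int = 36
    north: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.zone <= 60:
            raise ValueError(f"UTM zone must be in 1..60, got {self.zone}")

    @property
    def central_meridian_deg(self) -> float:
        return 6.0 * self.zone - 183.0

    @property
    def false_northing(self) -> float:
        return 0.0 if self.north else _FALSE_NORTHING_SOUTH

    @classmethod
    def parse(cls, spec: str) -> "UTMZone":
        """Parse a spec such as ``"36N"`` or ``"utm:36N"``."""
        s = spec.lower().removeprefix("utm:").strip()
        hemi = s[-1]
        if hemi not in "ns":
            raise ValueError(f"zone spec must end in N or S: {spec!r}")
        return cls(zone=int(s[:-1]), north=hemi == "n")


def utm_forward(lon, lat, zone: UTMZone = UTMZone()):
    """Project WGS84 lon/lat (degrees) to UTM easting/northing (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    lam = np.radians(lon - zone.central_meridian_deg)

    sphi = np.sin(phi)
    # conformal latitude
    t = np.sinh(np.arctanh(sphi) - _ECC * np.arctanh(_ECC * sphi))
    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _A_RECT * eta
    northing = zone.false_northing + _K0 * _A_RECT * xi
    return easting, northing


def utm_inverse(easting, northing, zone: UTMZone = UTMZone()):
    """Inverse projection: UTM easting/northing (m) back to lon/lat (deg)."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = (northing - zone.false_northing) / (_K0 * _A_RECT)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_RECT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    schi = np.sin(xi_p) / np.cosh(eta_p)  # sine of conformal latitude
    # invert the conformal latitude by fixed-point iteration (converges
    # geometrically with ratio ~e^2 ~ 6.7e-3; 12 rounds is far past double
    # precision)
    sphi = schi
    for _ in range(12):
        sphi = np.tanh(np.arctanh(schi) + _ECC * np.arctanh(_ECC * sphi))
    phi = np.arcsin(np.clip(sphi, -1.0, 1.0))

    lon = np.degrees(lam) + zone.central_meridian_deg
    lat = np.degrees(phi)
    return lon, lat


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

#: columns every track frame carries; x/y are NaN until projection
TRACK_COLUMNS = ["timestamp", "lon", "lat", "x", "y"]

AGE_CLASSES = ("<1 yr", "1-5 yr", ">5 yr")
SEX_STATUSES = ("intact male", "castrated male", "intact female", "spayed female")
TIME_OUTSIDE = ("<2 h", "2-6 h", ">6 h")


@dataclass
class SampledTrack:
    """One dog's ordered GPS fixes plus its household location.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware),
    ``lon``/``lat`` (WGS84 degrees) and ``x``/``y`` (planar metres, NaN
    until projected).  ``household_xy`` is the household in the same
    planar frame; ``household_lonlat`` the geographic equivalent.
    """

    dog_id: str
    fixes: pd.DataFrame
    household_lonlat: tuple[float, float] | None = None
    household_xy: tuple[float, float] | None = None
    zone: UTMZone = field(default_factory=UTMZone)

    def __post_init__(self) -> None:
        missing = [c for c in ("timestamp", "lon", "lat") if c not in self.fixes]
        if missing:
            raise ValueError(f"track frame missing columns {missing}")
        for c in ("x", "y"):
            if c not in self.fixes:
                self.fixes[c] = np.nan
        if len(self.fixes) < 1:
            raise ValueError(f"track {self.dog_id!r} has no fixes")

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def is_projected(self) -> bool:
        return bool(np.isfinite(self.fixes["x"]).all())

    @property
    def recording_hours(self) -> float:
        """Elapsed span between first and last fix, in hours."""
        ts = self.fixes["timestamp"]
        return (ts.iloc[-1] - ts.iloc[0]).total_seconds() / 3600.0

    def xy(self) -> np.ndarray:
        """(n, 2) planar coordinates; raises if not yet projected."""
        if not self.is_projected:
            raise ValueError(f"track {self.dog_id!r} has not been projected")
        return self.fixes[["x", "y"]].to_numpy(dtype=float)

    def times_s(self) -> np.ndarray:
        """Seconds since the first fix, as float."""
        ts = self.fixes["timestamp"]
        return (ts - ts.iloc[0]).dt.total_seconds().to_numpy(dtype=float)

    def copy(self) -> "SampledTrack":
        return replace(self, fixes=self.fixes.copy().reset_index(drop=True))


@dataclass(frozen=True)
class DogMetadata:
    """Questionnaire covariates for one dog."""

    dog_id: str
    site: str
    age_class: str
    sex_status: str
    reported_time_outside: str
    purpose: str = "security"
    feeding_frequency: str = "daily"

    def __post_init__(self) -> None:
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"age_class must be one of {AGE_CLASSES}")
        if self.sex_status not in SEX_STATUSES:
            raise ValueError(f"sex_status must be one of {SEX_STATUSES}")
        if self.reported_time_outside not in TIME_OUTSIDE:
            raise ValueError(f"reported_time_outside must be one of {TIME_OUTSIDE}")


# ---------------------------------------------------------------------------
# Logger CSV dialect and reading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoggerDialect:
    """Column mapping and time conventions of a logger CSV export.

    The default matches the files written by the synthetic module (and is
    shaped like a typical collar export): index, ISO 8601 date-time,
    latitude, longitude, elevation.  ``timezone`` is applied to naive
    timestamps; the study loggers ran on East Africa Time (UTC+3).
    """

    timestamp_col: str = "datetime"
    lat_col: str = "latitude"
    lon_col: str = "longitude"
    elevation_col: str | None = "elevation"
    timezone: str = "Etc/GMT-3"  # POSIX sign convention: UTC+3
    timestamp_format: str | None = None


DEFAULT_DIALECT = LoggerDialect()


def read_logger_csv(
    path,
    dog_id: str | None = None,
    dialect: LoggerDialect = DEFAULT_DIALECT,
    household_lonlat: tuple[float, float] | None = None,
) -> SampledTrack:
    """Read one dog's logger CSV into a :class:`SampledTrack`.

    Fixes are sorted by time and exact duplicate timestamps collapsed to
    the first occurrence (logged).  Raises :class:`ValueError` naming the
    offending row for missing columns or unparseable timestamps.
    """
    raw = pd.read_csv(path)
    needed = [dialect.timestamp_col, dialect.lat_col, dialect.lon_col]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    ts = pd.to_datetime(
        raw[dialect.timestamp_col], format=dialect.timestamp_format, errors="coerce"
    )
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        # +2: 1-based, plus the header line
        raise ValueError(
            f"{path}: unparseable timestamp at row {bad[0] + 2} "
            f"({raw[dialect.timestamp_col].iloc[bad[0]]!r})"
        )
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(dialect.timezone)

    lat = pd.to_numeric(raw[dialect.lat_col], errors="coerce")
    lon = pd.to_numeric(raw[dialect.lon_col], errors="coerce")
    if lat.isna().any() or lon.isna().any():
        row = int(np.flatnonzero((lat.isna() | lon.isna()).to_numpy())[0])
        raise ValueError(f"{path}: non-numeric coordinate at row {row + 2}")
    if (lat.abs() > 90).any() or (lon.abs() > 180).any():
        raise ValueError(f"{path}: coordinates outside valid lat/lon range")

    frame = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat})
    n_raw = len(frame)
    frame = frame.sort_values("timestamp", kind="stable")
    dup = frame["timestamp"].duplicated(keep="first")
    if dup.any():
        logger.warning(
            "%s: collapsed %d duplicate-timestamp fixes (kept first)",
            path, int(dup.sum()),
        )
        frame = frame[~dup]
    frame = frame.reset_index(drop=True)
    logger.info("%s: read %d rows, %d fixes retained", path, n_raw, len(frame))

    if dog_id is None:
        dog_id = _stem(path)
    return SampledTrack(dog_id=dog_id, fixes=frame, household_lonlat=household_lonlat)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def project_to_planar(track: SampledTrack, zone: UTMZone | str = UTMZone()) -> SampledTrack:
    """Fill planar ``x``/``y`` (m) for every fix under a UTM projection.

    The household, when present in geographic coordinates, is projected
    into the same frame.  Fixes far outside the nominal zone extent
    (central meridian +- ~3.5 deg) trigger a warning, not an error:
    transverse Mercator degrades gracefully and adjacent-zone use is
    deliberately supported.
    """
    if isinstance(zone, str):
        zone = UTMZone.parse(zone)
    out = track.copy()
    lon = out.fixes["lon"].to_numpy(dtype=float)
    lat = out.fixes["lat"].to_numpy(dtype=float)
    if np.any(np.abs(lon - zone.central_meridian_deg) > 3.5):
        warnings.warn(
            f"track {track.dog_id!r}: fixes more than 3.5 deg from the zone "
            f"{zone.zone}{'N' if zone.north else 'S'} central meridian; "
            "distances remain usable but consider the neighbouring zone",
            stacklevel=2,
        )
    x, y = utm_forward(lon, lat, zone)
    out.fixes["x"] = x
    out.fixes["y"] = y
    out.zone = zone
    if out.household_lonlat is not None:
        hx, hy = utm_forward(*out.household_lonlat, zone)
        out.household_xy = (float(hx), float(hy))
    return out


# ---------------------------------------------------------------------------
# Metadata and track CSV round-trip
# ---------------------------------------------------------------------------

def read_metadata_csv(path) -> dict[str, DogMetadata]:
    """Read the per-dog questionnaire table keyed by ``dog_id``."""
    table = pd.read_csv(path, dtype=str)
    needed = ["dog_id", "site", "age_class", "sex_status", "reported_time_outside"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    out: dict[str, DogMetadata] = {}
    for _, row in table.iterrows():
        md = DogMetadata(
            dog_id=row["dog_id"],
            site=row["site"],
            age_class=row["age_class"],
            sex_status=row["sex_status"],
            reported_time_outside=row["reported_time_outside"],
            purpose=row.get("purpose", "security"),
            feeding_frequency=row.get("feeding_frequency", "daily"),
        )
        out[md.dog_id] = md
    return out


def write_track_csv(track: SampledTrack, path) -> None:
    """Write a (cleaned) track back to RFC 4180 CSV in logger layout."""
    frame = pd.DataFrame(
        {
            "index": np.arange(1, track.n_fixes + 1),
            "datetime": track.fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "latitude": track.fixes["lat"].round(9),
            "longitude": track.fixes["lon"].round(9),
            "elevation": 0.0,
        }
    )
    frame.to_csv(path, index=False, lineterminator="\r\n")
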