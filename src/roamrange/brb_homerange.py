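"""Movement-based (biased random bridge) utilization distribution.

The utilization distribution (UD) is estimated with a movement kernel
that links successive fixes: along each step of duration ``T <= Tmax``
and length ``>= Lmin``, Gaussian mass is deposited at ``n_substeps``
interpolated positions ``p in (0, 1)``, each carrying weight
``T / n_substeps`` and isotropic variance

    sigma^2(p) = hmin^2 + 4 * D * T * p * (1 - p),

i.e. Brownian-bridge scaling — zero movement variance at the fix times,
maximal mid-step — floored by ``hmin`` for GPS error.  Steps longer than
``Tmax`` (un-bridgeable gaps, predominantly rest) or shorter than
``Lmin`` (no real movement) deposit their weight at the two endpoint
fixes (half each) with variance ``hmin^2``.  Total mass is normalized to
1 on a raster grid covering the track's bounding box plus a pad.

Home ranges are read off the UD as isopleths: the smallest set of cells
holding a stated fraction of the mass (50% = core, 95% = extended), with
areas in hectares and one centroid — the arithmetic mean of member-cell
centres — per connected polygon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .trajectory_io import SampledTrack, UTMZone, utm_inverse

logger = logging.getLogger("roamrange")

HA_PER_M2 = 1e-4
DEFAULT_LEVELS = (10.0, 50.0, 90.0, 95.0)


@dataclass(frozen=True)
class BRBParams:
    """Smoothing and discretisation parameters of the movement kernel.

    diffusion_D      m^2/s; None -> plug-in estimate from the track
    hmin             minimum smoothing (GPS error scale), m
    tmax_s           maximum step duration to bridge; None -> 3 x median
                     fix interval of the track
    lmin             minimum step length treated as real movement, m
    cell_size        raster cell edge, m
    extent_pad       margin added around the track bounding box, m
    n_substeps       interpolated kernel positions per bridged step
    trunc_sigmas     kernel evaluation radius in sigmas (9 keeps the
                     truncated tail below double-precision noise)
    max_cells        guard on grid size
    """

    diffusion_D: float | None = None
    hmin: float = 25.0
    tmax_s: float | None = None
    lmin: float = 5.0
    cell_size: float = 10.0
    extent_pad: float = 200.0
    n_substeps: int = 10
    trunc_sigmas: float = 9.0
    max_cells: int = 4_000_000

    def __post_init__(self) -> None:
        if self.hmin <= 0 or self.lmin <= 0 or self.cell_size <= 0:
            raise ValueError("hmin, lmin and cell_size must be positive")
        if self.extent_pad < self.cell_size:
            raise ValueError("extent_pad must be at least one cell")
        if self.n_substeps < 1:
            raise ValueError("n_substeps must be >= 1")


@dataclass
class UDGrid:
    """Raster probability mass over planar space.

    ``mass[i, j]`` is the probability in the cell whose centre is
    ``(origin_x + (j + .5) * cell, origin_y + (i + .5) * cell)`` — row 0
    is the southern edge.  Mass sums to 1.
    """

    origin: tuple[float, float]
    cell_size: float
    mass: np.ndarray
    params: BRBParams | None = None

    @property
    def n_rows(self) -> int:
        return self.mass.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mass.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.origin[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys


@dataclass
class IsoplethSet:
    """Nested home-range contour at one probability level."""

    level: float
    cell_mask: np.ndarray            # boolean over the UD grid
    polygons: list                   # shapely Polygons (one per component)
    polygon_areas_m2: list[float]    # cell-count area per polygon
    centroids_xy: list[tuple[float, float]]
    total_area_ha: float
    grid: UDGrid
    centroids_lonlat: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Diffusion estimate
# ---------------------------------------------------------------------------

def estimate_diffusion(track: SampledTrack, params: BRBParams = BRBParams()) -> float:
    """Plug-in movement-intensity estimate D-hat = mean(L^2 / (4 T)).

    Averaged over steps with duration <= tmax_s and length >= lmin.
    Raises if no step qualifies (fix D explicitly in that case).
    """
    xy = track.xy()
    t = track.times_s()
    if len(xy) < 2:
        raise ValueError("need at least 2 fixes to estimate diffusion")
    L = np.hypot(*np.diff(xy, axis=0).T)
    T = np.diff(t)
    tmax = _resolve_tmax(params, T)
    ok = (T > 0) & (T <= tmax) & (L >= params.lmin)
    if not ok.any():
        raise ValueError(
            "no steps qualify for the diffusion estimate "
            "(all too long, too short, or instantaneous); set BRBParams.diffusion_D"
        )
    return float(np.mean(L[ok] ** 2 / (4.0 * T[ok])))


def _resolve_tmax(params: BRBParams, step_durations: np.ndarray) -> float:
    if params.tmax_s is not None:
        return params.tmax_s
    pos = step_durations[step_durations > 0]
    return 3.0 * float(np.median(pos)) if pos.size else math.inf


# ---------------------------------------------------------------------------
# UD construction
# ---------------------------------------------------------------------------

def _kernel_deposits(
    xy: np.ndarray, t: np.ndarray, params: BRBParams, diffusion: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten the movement kernel into point deposits.

    Returns (positions (k, 2), weights (k,), sigmas (k,)).  Weights carry
    step durations (seconds) and are normalized later.  A single fix
    yields one unit-weight deposit at hmin.
    """
    if len(xy) == 1:
        return xy.copy(), np.array([1.0]), np.array([params.hmin])

    L = np.hypot(*np.diff(xy, axis=0).T)
    T = np.diff(t)
    tmax = _resolve_tmax(params, T)

    pos_list, w_list, s_list = [], [], []
    p = (np.arange(params.n_substeps) + 0.5) / params.n_substeps
    for i in range(len(L)):
        Ti = T[i]
        if Ti <= 0:
            continue
        if Ti <= tmax and L[i] >= params.lmin:
            # bridged: interpolate along the straight segment
            seg = xy[i] + p[:, None] * (xy[i + 1] - xy[i])
            var = params.hmin**2 + 4.0 * diffusion * Ti * p * (1.0 - p)
            pos_list.append(seg)
            w_list.append(np.full(params.n_substeps, Ti / params.n_substeps))
            s_list.append(np.sqrt(var))
        else:
            # rest gap or sub-Lmin jitter: mass at the endpoints
            pos_list.append(xy[i:i + 2])
            w_list.append(np.array([Ti / 2.0, Ti / 2.0]))
            s_list.append(np.array([params.hmin, params.hmin]))
    if not pos_list:
        # all steps zero-duration; degenerate to location kernel
        return xy.copy(), np.ones(len(xy)), np.full(len(xy), params.hmin)
    return np.vstack(pos_list), np.concatenate(w_list), np.concatenate(s_list)


def compute_brb_ud(
    track: SampledTrack, params: BRBParams = BRBParams()
) -> UDGrid:
    """Estimate the utilization distribution of one cleaned track."""
    xy = track.xy()
    t = track.times_s()
    if params.diffusion_D is not None:
        D = params.diffusion_D
    elif len(xy) >= 2:
        try:
            D = estimate_diffusion(track, params)
        except ValueError:
            logger.warning("%s: no qualifying steps; using D = 0 (pure hmin kernel)",
                           track.dog_id)
            D = 0.0
    else:
        D = 0.0

    x0 = xy[:, 0].min() - params.extent_pad
    x1 = xy[:, 0].max() + params.extent_pad
    y0 = xy[:, 1].min() - params.extent_pad
    y1 = xy[:, 1].max() + params.extent_pad
    n_cols = int(np.ceil((x1 - x0) / params.cell_size))
    n_rows = int(np.ceil((y1 - y0) / params.cell_size))
    if n_rows * n_cols > params.max_cells:
        raise ValueError(
            f"grid would need {n_rows * n_cols} cells (> {params.max_cells}); "
            "increase cell_size or reduce extent_pad"
        )

    grid = np.zeros((n_rows, n_cols))
    xs = x0 + (np.arange(n_cols) + 0.5) * params.cell_size
    ys = y0 + (np.arange(n_rows) + 0.5) * params.cell_size

    pos, w, sig = _kernel_deposits(xy, t, params, D)
    cell = params.cell_size
    for (px, py), wi, si in zip(pos, w, sig):
        # local window; trunc_sigmas=9 makes the discarded tail < 1e-17
        r = params.trunc_sigmas * si
        j0, j1 = np.searchsorted(xs, (px - r, px + r))
        i0, i1 = np.searchsorted(ys, (py - r, py + r))
        if j0 == j1 or i0 == i1:
            continue
        gx = np.exp(-0.5 * ((xs[j0:j1] - px) / si) ** 2)
        gy = np.exp(-0.5 * ((ys[i0:i1] - py) / si) ** 2)
        grid[i0:i1, j0:j1] += (wi * cell**2 / (2.0 * math.pi * si**2)) * np.outer(gy, gx)

    total = grid.sum()
    if total <= 0:
        raise ValueError("no kernel mass landed on the grid")
    grid /= total
    resolved = replace(params, diffusion_D=D,
                       tmax_s=_resolve_tmax(params, np.diff(t)) if len(t) > 1 else params.tmax_s)
    logger.info("%s: UD on %dx%d grid (cell %.0f m, D=%.3g m^2/s)",
                track.dog_id, n_rows, n_cols, cell, D)
    return UDGrid(origin=(x0, y0), cell_size=cell, mass=grid, params=resolved)


# ---------------------------------------------------------------------------
# Isopleths, areas, centroids
# ---------------------------------------------------------------------------

def isopleth_mask(ud: UDGrid, level: float) -> np.ndarray:
    """Smallest cell set holding >= level% of the UD mass (volume contour).

    Cells are ranked by mass descending, ties broken in row-major order
    for determinism.
    """
    if not 0.0 < level <= 100.0:
        raise ValueError(f"isopleth level must be in (0, 100], got {level}")
    if level == 100.0:
        return np.ones_like(ud.mass, dtype=bool)
    flat = ud.mass.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level / 100.0 - 1e-12)) + 1
    k = min(k, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.mass.shape)


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def extract_isopleth(ud: UDGrid, level: float, zone: UTMZone | None = None) -> IsoplethSet:
    """Volume contour at ``level`` % with polygons, areas and centroids.

    Selected cells are merged into disjoint polygons by 4-connectivity
    (diagonal-touching cells stay separate).  The centroid of each polygon
    is the unweighted mean of its member-cell centres; geographic
    centroids are filled when a UTM zone is given.
    """
    mask = isopleth_mask(ud, level)
    labels, n_poly = ndimage.label(mask, structure=_FOUR_CONN)
    xs, ys = ud.cell_centers()
    cell_area = ud.cell_size**2

    from shapely.geometry import box
    from shapely.ops import unary_union

    polygons, areas, centroids = [], [], []
    half = ud.cell_size / 2.0
    for lab in range(1, n_poly + 1):
        ii, jj = np.nonzero(labels == lab)
        cx = float(xs[jj].mean())
        cy = float(ys[ii].mean())
        centroids.append((cx, cy))
        areas.append(float(ii.size) * cell_area)
        boxes = [box(xs[j] - half, ys[i] - half, xs[j] + half, ys[i] + half)
                 for i, j in zip(ii, jj)]
        polygons.append(unary_union(boxes))

    iso = IsoplethSet(
        level=level,
        cell_mask=mask,
        polygons=polygons,
        polygon_areas_m2=areas,
        centroids_xy=centroids,
        total_area_ha=float(mask.sum()) * cell_area * HA_PER_M2,
        grid=ud,
    )
    if zone is not None and centroids:
        lons, lats = utm_inverse(
            np.array([c[0] for c in centroids]),
            np.array([c[1] for c in centroids]), zone,
        )
        iso.centroids_lonlat = list(zip(lons.tolist(), lats.tolist()))
    return iso


def isopleth_centroids(iso: IsoplethSet) -> list[tuple[float, float]]:
    """One planar centroid per polygon (arithmetic mean of cell centres)."""
    return list(iso.centroids_xy)


def home_range(
    track: SampledTrack,
    params: BRBParams = BRBParams(),
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> dict[float, IsoplethSet]:
    """UD + isopleths for one track; returns {level: IsoplethSet}."""
    ud = compute_brb_ud(track, params)
    return {lvl: extract_isopleth(ud, lvl, zone=track.zone) for lvl in levels}


# ---------------------------------------------------------------------------
# Plain-text raster / GeoJSON export
# ---------------------------------------------------------------------------

def write_ascii_grid(ud: UDGrid, path) -> None:
    """ESRI ASCII-grid compatible dump of the UD raster."""
    header = (
        f"ncols {ud.n_cols}\nnrows {ud.n_rows}\n"
        f"xllcorner {ud.origin[0]:.3f}\nyllcorner {ud.origin[1]:.3f}\n"
        f"cellsize {ud.cell_size:.3f}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grid rows run north -> south
        np.savetxt(fh, ud.mass[::-1], fmt="%.8e")


def isopleths_to_geojson(
    isopleths: dict[float, IsoplethSet], zone: UTMZone, dog_id: str = ""
) -> dict:
    """GeoJSON FeatureCollection (WGS84) of isopleth polygons + centroids."""
    feats = []
    for lvl, iso in sorted(isopleths.items()):
        for k, poly in enumerate(iso.polygons):
            rings = [list(poly.exterior.coords)] + [list(r.coords) for r in poly.interiors]
            ll_rings = []
            for ring in rings:
                arr = np.asarray(ring)
                lon, lat = utm_inverse(arr[:, 0], arr[:, 1], zone)
                ll_rings.append([[round(a, 8), round(b, 8)] for a, b in zip(lon, lat)])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": ll_rings},
                "properties": {
                    "dog_id": dog_id, "level_pct": lvl, "polygon": k,
                    "area_m2": round(iso.polygon_areas_m2[k], 2),
                },
            })
            cx, cy = iso.centroids_xy[k]
            lon, lat = utm_inverse(cx, cy, zone)
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [round(float(lon), 8), round(float(lat), 8)]},
                "properties": {"dog_id": dog_id, "level_pct": lvl, "polygon": k,
                               "role": "centroid"},
            })
    return {"type": "FeatureCollection", "features": feats}
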