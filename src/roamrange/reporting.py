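"""Study-level outputs: per-site summary tables, centroid inventories
for ground-truthing, and cross-dog centroid overlap flags."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .movement_metrics import MovementSummary
from .trajectory_io import DogMetadata

logger = logging.getLogger("roamrange")

#: isopleth levels surveyed on the ground (the 95% level is analysis-only)
CENTROID_LEVELS = (10.0, 50.0, 90.0)


@dataclass(frozen=True)
class CentroidRecord:
    """One isopleth-polygon centroid, ready for a field visit."""

    dog_id: str
    level: float
    lon: float
    lat: float
    x: float
    y: float
    polygon_area_m2: float
    label: str = ""  # filled by hand after ground-truthing

    def __post_init__(self) -> None:
        if self.level not in CENTROID_LEVELS:
            raise ValueError(
                f"centroid inventory covers levels {CENTROID_LEVELS}, got {self.level}"
            )


def site_summary(
    summaries: list[MovementSummary], metadata: dict[str, DogMetadata]
) -> pd.DataFrame:
    """Per-site medians of the four outcomes, plus an overall row."""
    rows = []
    for s in summaries:
        md = metadata[s.dog_id]
        rows.append({
            "site": md.site,
            "dog_id": s.dog_id,
            "daily_distance_km": s.daily_distance_km,
            "core_hr_ha": s.core_hr_ha,
            "extended_hr_ha": s.extended_hr_ha,
            "pct_time_household": s.pct_time_household,
        })
    per_dog = pd.DataFrame(rows)
    cols = ["daily_distance_km", "core_hr_ha", "extended_hr_ha", "pct_time_household"]
    out = (
        per_dog.groupby("site")
        .agg(n_dogs=("dog_id", "size"), **{f"median_{c}": (c, "median") for c in cols})
        .reset_index()
        .sort_values("site", kind="stable")
    )
    overall = {"site": "Overall", "n_dogs": len(per_dog)}
    overall.update({f"median_{c}": float(per_dog[c].median()) for c in cols})
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)


def centroid_records(per_dog_isopleths: dict[str, dict]) -> list[CentroidRecord]:
    """Flatten {dog_id: {level: IsoplethSet}} into the centroid inventory."""
    records = []
    for dog_id, by_level in per_dog_isopleths.items():
        for level in CENTROID_LEVELS:
            iso = by_level.get(level)
            if iso is None:
                continue
            for k, (x, y) in enumerate(iso.centroids_xy):
                lon, lat = (iso.centroids_lonlat[k]
                            if iso.centroids_lonlat else (float("nan"), float("nan")))
                records.append(CentroidRecord(
                    dog_id=dog_id, level=level,
                    lon=float(lon), lat=float(lat), x=float(x), y=float(y),
                    polygon_area_m2=iso.polygon_areas_m2[k],
                ))
    return records


def centroid_overlap(
    records: list[CentroidRecord], distance_threshold_m: float = 50.0
) -> pd.DataFrame:
    """Dog pairs with any pair of centroids closer than the threshold.

    Flags putative shared locations (e.g. two dogs using the same rubbish
    dump).  The relation is symmetric; each unordered dog pair appears
    once with its closest qualifying centroid pair.
    """
    by_dog: dict[str, list[CentroidRecord]] = {}
    for r in records:
        by_dog.setdefault(r.dog_id, []).append(r)
    dogs = sorted(by_dog)
    if len(dogs) < 2:
        raise ValueError("need centroid records for at least 2 dogs")
    rows = []
    for i, a in enumerate(dogs):
        pa = np.array([(r.x, r.y) for r in by_dog[a]])
        for b in dogs[i + 1:]:
            pb = np.array([(r.x, r.y) for r in by_dog[b]])
            dm = cdist(pa, pb)
            ia, ib = np.unravel_index(np.argmin(dm), dm.shape)
            if dm[ia, ib] <= distance_threshold_m:
                ra, rb = by_dog[a][ia], by_dog[b][ib]
                rows.append({
                    "dog_a": a, "dog_b": b,
                    "distance_m": float(dm[ia, ib]),
                    "level_a": ra.level, "level_b": rb.level,
                    "lon": (ra.lon + rb.lon) / 2.0, "lat": (ra.lat + rb.lat) / 2.0,
                    "x": (ra.x + rb.x) / 2.0, "y": (ra.y + rb.y) / 2.0,
                })
    return pd.DataFrame(rows, columns=["dog_a", "dog_b", "distance_m",
                                       "level_a", "level_b", "lon", "lat", "x", "y"])


def summarize_centroid_labels(records: list[CentroidRecord]) -> pd.DataFrame:
    """Label frequencies (%) per isopleth level, from field-entered labels.

    Rows are labels, columns levels; unlabeled records are ignored.  The
    package never infers land use — labels come from ground visits.
    """
    labelled = [r for r in records if r.label]
    if not labelled:
        return pd.DataFrame()
    frame = pd.DataFrame({"label": [r.label for r in labelled],
                          "level": [r.level for r in labelled]})
    counts = frame.pivot_table(index="label", columns="level",
                               aggfunc="size", fill_value=0)
    return counts / counts.sum(axis=0) * 100.0


def centroids_to_csv(records: list[CentroidRecord], path) -> None:
    pd.DataFrame([{
        "dog_id": r.dog_id, "isopleth_level_pct": r.level,
        "lon": r.lon, "lat": r.lat, "x_m": r.x, "y_m": r.y,
        "polygon_area_m2": r.polygon_area_m2, "label": r.label,
    } for r in records]).to_csv(path, index=False)


def centroids_to_geojson(records: list[CentroidRecord], path=None) -> dict:
    fc = {
        "type": "FeatureCollection",
        "features": [{
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(r.lon, 8), round(r.lat, 8)]},
            "properties": {"dog_id": r.dog_id, "level_pct": r.level,
                           "polygon_area_m2": round(r.polygon_area_m2, 2),
                           "label": r.label},
        } for r in records],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh, indent=1)
    return fc
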