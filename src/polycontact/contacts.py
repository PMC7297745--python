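"""Pairwise distances, contact detection and bout extraction.

Given an oriented-polygon series (or a point fix table), this module computes
inter-individual distances per timestep for the requested body-part pairings,
flags contacts under a spatial threshold (SpTh, inclusive: distance <= SpTh),
and collapses per-timestep flags into maximal contact bouts on the fixed
temporal grid.

Distances are minimum Euclidean separations between geometries: zero when
geometries intersect or one contains the other.  A missing fix at a timestep
produces no distance record (never a zero distance) and, by default, breaks
any ongoing bout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .io import ID_COL, TIME_COL, X_COL, Y_COL, ConfigurationError, GeometryError
from .geometry import PART_COL
from .preprocess import GridSpec

POINT_PART = "point"

DISTANCE_COLUMNS = [TIME_COL, "id_a", "part_a", "id_b", "part_b", "directed", "distance"]
BOUT_COLUMNS = [
    "id_a",
    "part_a",
    "id_b",
    "part_b",
    "directed",
    "start_time",
    "end_time",
    "n_timesteps",
]


def _as_geometry(g):
    if isinstance(g, shapely.Geometry):
        geom = g
    else:
        geom = Point(g)
    if not geom.is_valid:
        raise GeometryError(f"invalid geometry: {shapely.is_valid_reason(geom)}")
    return geom


def geometry_distance(g1, g2) -> float:
    """Minimum Euclidean distance between two planar geometries (meters).

    Accepts shapely points/polygons or (x, y) tuples.  Returns 0 when the
    geometries intersect or one contains the other.
    """
    return float(_as_geometry(g1).distance(_as_geometry(g2)))


def _series_from_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    out = fixes[[ID_COL, TIME_COL]].copy()
    out[PART_COL] = POINT_PART
    out["geometry"] = shapely.points(
        fixes[X_COL].to_numpy(float), fixes[Y_COL].to_numpy(float)
    )
    return out


def pairwise_distances(
    series: pd.DataFrame,
    pairing: list[tuple[str, str]],
    directed: bool = False,
) -> pd.DataFrame:
    """Inter-individual distances per timestep for the requested part pairs.

    ``series`` is an oriented-polygon series (``id``/``time``/``part``/
    ``geometry``) or a planar fix table (points get the part name
    ``"point"``).  ``pairing`` lists (part_a, part_b) combinations.

    Undirected pairings with ``part_a == part_b`` yield one record per
    unordered pair of distinct individuals; with ``part_a != part_b`` both
    part-to-part combinations are emitted, ``id_a`` always owning ``part_a``.
    Directed pairings yield one record per ordered pair — the point-in-polygon
    visual relation is not symmetric and is never symmetrized.  Self-pairs
    (same individual, any parts) are always excluded.
    """
    if "geometry" not in series.columns:
        series = _series_from_fixes(series)
    present = set(series[PART_COL].unique())
    wanted = {p for pair in pairing for p in pair}
    missing = wanted - present
    if missing:
        raise ConfigurationError(f"parts {sorted(missing)} absent from series")

    records = []
    for t, frame in series.groupby(TIME_COL, sort=True):
        geoms = {(row.id, row.part): row.geometry for row in frame.itertuples()}
        ids = sorted({row.id for row in frame.itertuples()})
        for part_a, part_b in pairing:
            if directed:
                ordered = [(a, b) for a in ids for b in ids if a != b]
            elif part_a == part_b:
                ordered = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
            else:
                ordered = [(a, b) for a in ids for b in ids if a != b]
            for a, b in ordered:
                ga = geoms.get((a, part_a))
                gb = geoms.get((b, part_b))
                if ga is None or gb is None:
                    continue
                records.append(
                    (t, a, part_a, b, part_b, directed, float(ga.distance(gb)))
                )
    return pd.DataFrame(records, columns=DISTANCE_COLUMNS)


def detect_contacts(dist: pd.DataFrame, spth: float) -> pd.DataFrame:
    """Flag contacts: distance <= spth (inclusive threshold)."""
    if spth < 0:
        raise ConfigurationError("spth must be >= 0")
    out = dist.copy()
    out["contact"] = out["distance"] <= spth
    return out


def extract_bouts(
    flags: pd.DataFrame, grid: GridSpec, max_gap: int = 0
) -> pd.DataFrame:
    """Collapse per-timestep contact flags into maximal bouts.

    A bout is a maximal run of grid-consecutive in-contact timesteps for one
    (id_a, part_a, id_b, part_b) combination.  Runs separated by at most
    ``max_gap`` non-contact or missing timesteps are merged when
    ``max_gap > 0``; the default 0 requires strict consecutiveness.
    ``n_timesteps`` counts the in-contact timesteps of the bout (equal to
    ``(end_time - start_time) / interval + 1`` when no gaps were merged).
    """
    if max_gap < 0:
        raise ConfigurationError("max_gap must be >= 0")
    rows = []
    contact = flags[flags["contact"]]
    keys = ["id_a", "part_a", "id_b", "part_b", "directed"]
    for key, sub in contact.groupby(keys, sort=True):
        times = np.sort(sub[TIME_COL].unique())
        start = prev = times[0]
        count = 1
        for t in times[1:]:
            gap_steps = (t - prev) // grid.interval - 1
            if gap_steps <= max_gap:
                prev = t
                count += 1
            else:
                rows.append((*key, start, prev, count))
                start = prev = t
                count = 1
        rows.append((*key, start, prev, count))
    out = pd.DataFrame(
        rows,
        columns=["id_a", "part_a", "id_b", "part_b", "directed", "start_time", "end_time", "n_timesteps"],
    )
    return out[BOUT_COLUMNS] if len(out) else pd.DataFrame(columns=BOUT_COLUMNS)
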