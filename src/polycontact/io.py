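"""Reading, writing and projecting RTLS trajectory tables, polygons and networks.

Trajectory tables ("fix tables") are plain :class:`pandas.DataFrame` objects
with columns ``id`` (individual identifier, string), ``time`` (integer seconds
since the epoch), ``x`` and ``y`` (meters in a planar frame, or degrees
longitude/latitude).  The coordinate system is recorded in ``df.attrs["crs"]``
as ``"planar"`` or ``"geographic"``; all geometric operations downstream
require planar input.

Geographic tables are brought into a planar frame with an azimuthal
equidistant projection centered on the data centroid, which preserves
distances from the projection center exactly — the property that matters when
the center sits inside the study area and inter-individual distances are small
relative to the Earth's radius.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape

logger = logging.getLogger("polycontact")

ID_COL = "id"
TIME_COL = "time"
X_COL = "x"
Y_COL = "y"
FIX_COLUMNS = [ID_COL, TIME_COL, X_COL, Y_COL]

PLANAR = "planar"
GEOGRAPHIC = "geographic"

#: mean Earth radius in meters used by the azimuthal equidistant projection
EARTH_RADIUS_M = 6_371_000.0


class ConfigurationError(ValueError):
    """A parameter or input schema is invalid."""


class InputError(ValueError):
    """Input data are unusable (e.g., empty after parsing)."""


class GeometryError(ValueError):
    """A geometry is malformed (e.g., self-intersecting ring)."""


# ---------------------------------------------------------------------------
# fix tables
# ---------------------------------------------------------------------------

#: aliases tried, in order, when no explicit column map is given
_COLUMN_ALIASES = {
    "individual_id": ("id", "individual_id", "individual-local-identifier"),
    "time": ("time", "ts", "timestamp"),
    "x": ("x", "location-long", "lon", "longitude"),
    "y": ("y", "location-lat", "lat", "latitude"),
}
_GEOGRAPHIC_HINTS = ("lon", "lat")


def make_fixes(records, coordinate_system: str = PLANAR) -> pd.DataFrame:
    """Build a fix table from records of ``(id, time, x, y)``.

    Rows are sorted by ``(id, time)``; ``time`` is coerced to integer seconds.
    """
    df = pd.DataFrame(records, columns=FIX_COLUMNS)
    df[ID_COL] = df[ID_COL].astype(str)
    df[TIME_COL] = df[TIME_COL].astype(np.int64)
    df[X_COL] = df[X_COL].astype(float)
    df[Y_COL] = df[Y_COL].astype(float)
    df = df.sort_values([ID_COL, TIME_COL], kind="stable").reset_index(drop=True)
    df.attrs["crs"] = coordinate_system
    return df


def coordinate_system(fixes: pd.DataFrame) -> str:
    """Coordinate system recorded on a fix table (defaults to planar)."""
    return fixes.attrs.get("crs", PLANAR)


def _resolve_columns(columns, column_map):
    resolved = {}
    if column_map is not None:
        for canonical in _COLUMN_ALIASES:
            source = column_map.get(canonical)
            if source is None or source not in columns:
                raise ConfigurationError(
                    f"mapped column for {canonical!r} ({source!r}) not found in file"
                )
            resolved[canonical] = source
        return resolved
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in columns:
                resolved[canonical] = alias
                break
        else:
            raise ConfigurationError(
                f"could not find a column for {canonical!r}; supply column_map"
            )
    return resolved


def _parse_times(raw: pd.Series) -> pd.Series:
    numeric = pd.to_numeric(raw, errors="coerce")
    if numeric.notna().all():
        return numeric
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="mixed")
    seconds = parsed.astype("int64").where(parsed.notna()) // 10**9
    return seconds.astype(float)


def read_fixes(path, column_map=None, coordinate_system_hint=None) -> pd.DataFrame:
    """Read a trajectory CSV into a fix table.

    Parameters
    ----------
    path :
        CSV file with a header row.
    column_map :
        Optional mapping from the canonical names ``individual_id``, ``time``,
        ``x``, ``y`` to the file's column names (Movebank exports, for
        instance, use ``individual-local-identifier``/``timestamp``/
        ``location-long``/``location-lat``).  When omitted, common aliases are
        tried.
    coordinate_system_hint :
        Force ``"planar"`` or ``"geographic"``; by default the table is marked
        geographic when the x/y source column names mention lon/lat.

    Rows whose coordinates or timestamps cannot be parsed are dropped; the
    count is logged and stored in ``df.attrs["rows_dropped"]``.  Timestamps are
    parsed as UTC and held as integer epoch seconds.
    """
    raw = pd.read_csv(path, dtype=str)
    resolved = _resolve_columns(raw.columns, column_map)
    out = pd.DataFrame(
        {
            ID_COL: raw[resolved["individual_id"]].astype(str),
            TIME_COL: _parse_times(raw[resolved["time"]]),
            X_COL: pd.to_numeric(raw[resolved["x"]], errors="coerce"),
            Y_COL: pd.to_numeric(raw[resolved["y"]], errors="coerce"),
        }
    )
    ok = out[[TIME_COL, X_COL, Y_COL]].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_fixes: dropped %d unparseable rows from %s", n_dropped, path)
    out = out[ok]
    if out.empty:
        raise InputError(f"no parseable fixes in {path}")
    if coordinate_system_hint is not None:
        crs = coordinate_system_hint
    else:
        hint_cols = (resolved["x"] + " " + resolved["y"]).lower()
        crs = GEOGRAPHIC if any(h in hint_cols for h in _GEOGRAPHIC_HINTS) else PLANAR
    fixes = make_fixes(out, coordinate_system=crs)
    fixes.attrs["rows_dropped"] = n_dropped
    return fixes


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write a fix table as CSV with columns id,time,x,y."""
    fixes[FIX_COLUMNS].to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# planar projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectionSpec:
    """Azimuthal equidistant projection centered at (center_lon, center_lat)."""

    center_lon: float
    center_lat: float
    method: str = "azimuthal_equidistant"

    def __post_init__(self):
        if not (math.isfinite(self.center_lon) and math.isfinite(self.center_lat)):
            raise ConfigurationError("projection center must be finite")
        if abs(self.center_lat) > 90:
            raise ConfigurationError("|center_lat| must be <= 90")
        if self.method != "azimuthal_equidistant":
            raise ConfigurationError(f"unsupported projection method {self.method!r}")


def project_to_plane(fixes: pd.DataFrame, spec="centroid") -> pd.DataFrame:
    """Project a geographic fix table onto a plane (azimuthal equidistant).

    With ``spec="centroid"`` the projection is centered on the arithmetic mean
    of all longitudes/latitudes.  The projection maps the center to the origin
    and preserves great-circle distances from the center exactly (spherical
    Earth, radius :data:`EARTH_RADIUS_M`).  Records at the poles or at the
    center's antipode (where the projection is singular) are dropped with a
    logged count.
    """
    if coordinate_system(fixes) != GEOGRAPHIC:
        raise ConfigurationError("project_to_plane requires a geographic fix table")
    if spec == "centroid":
        spec = ProjectionSpec(float(fixes[X_COL].mean()), float(fixes[Y_COL].mean()))
    lam = np.radians(fixes[X_COL].to_numpy(float))
    phi = np.radians(fixes[Y_COL].to_numpy(float))
    lam0 = math.radians(spec.center_lon)
    phi0 = math.radians(spec.center_lat)

    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    # k = c / sin(c), -> 1 as c -> 0; singular at the antipode (c = pi)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 0, c / np.sin(c), 1.0)
    bad = (c >= math.pi - 1e-12) | (np.abs(phi) >= math.pi / 2 - 1e-12)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("project_to_plane: dropped %d singular records", n_bad)
    out = fixes.copy()
    out[X_COL] = x
    out[Y_COL] = y
    out = out[~bad].reset_index(drop=True)
    out.attrs["crs"] = PLANAR
    out.attrs["projection"] = spec
    return out


# ---------------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------------

POLYGON_COLUMNS = [ID_COL, TIME_COL, "part", "heading"]


def write_polygons(series: pd.DataFrame, path, format: str = "wkt-csv") -> None:
    """Write an oriented-polygon series.

    ``format="wkt-csv"`` writes one row per (individual, time, part) with a
    WKT ``POLYGON`` column (rings closed); ``format="geojson"`` writes a
    FeatureCollection with ``id``, ``time``, ``part`` and ``heading``
    properties.
    """
    if series.empty:
        raise InputError("cannot write an empty polygon series")
    if format == "wkt-csv":
        out = series[POLYGON_COLUMNS].copy()
        out["wkt"] = [g.wkt for g in series["geometry"]]
        out.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC)
    elif format == "geojson":
        features = [
            {
                "type": "Feature",
                "geometry": shapely_mapping(row.geometry),
                "properties": {
                    "id": row.id,
                    "time": int(row.time),
                    "part": row.part,
                    "heading": float(row.heading),
                },
            }
            for row in series.itertuples()
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        raise ConfigurationError(f"unknown polygon format {format!r}")


def read_polygons(path, format: str = "wkt-csv") -> pd.DataFrame:
    """Read a polygon series written by :func:`write_polygons`."""
    if format == "wkt-csv":
        raw = pd.read_csv(path, dtype={ID_COL: str})
        raw["geometry"] = [shapely_wkt.loads(w) for w in raw.pop("wkt")]
        return raw
    if format == "geojson":
        with open(path) as fh:
            collection = json.load(fh)
        rows = []
        for feat in collection["features"]:
            props = feat["properties"]
            rows.append(
                {
                    ID_COL: str(props["id"]),
                    TIME_COL: int(props["time"]),
                    "part": props["part"],
                    "heading": props["heading"],
                    "geometry": shapely_shape(feat["geometry"]),
                }
            )
        return pd.DataFrame(rows)
    raise ConfigurationError(f"unknown polygon format {format!r}")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

NETWORK_COLUMNS = ["from_id", "to_id", "from_part", "to_part", "directed", "weight"]


def write_network(net, path) -> None:
    """Write a contact network as an edge-list CSV in deterministic order.

    One row per aggregated edge; bout-level duplicates are summed into edge
    weights before writing, so an edge never appears twice.
    """
    rows = net.edge_records()
    rows.sort(key=lambda r: (r["from_id"], r["to_id"], r["from_part"], r["to_part"]))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=NETWORK_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


def read_network(path) -> pd.DataFrame:
    """Read an edge-list CSV written by :func:`write_network`."""
    return pd.read_csv(path, dtype={"from_id": str, "to_id": str})
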