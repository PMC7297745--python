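"""Heading estimation and derivation of oriented polygons from point fixes.

A *planar model* is a template: one or more polygon parts drawn in a local
frame around a reference point (the tracking-device location on the animal's
body), together with the template's forward direction ``eta*``.  At each
timestep an individual's reported point location is turned into empirical
polygons by rigidly translating and rotating the template so that the
reference point sits on the fix and the forward direction aligns with the
individual's estimated heading ``eta_it``.

Headings are estimated from relocations: the heading at time ``t`` is the
absolute angle (degrees counter-clockwise from the +x axis) of the vector
from the most recent *qualifying* previous location to the current one.  A
relocation qualifies only when its displacement from the last update point
reaches the *immobility threshold*; smaller jitter (head shaking, positional
noise) leaves both the polygon position and orientation frozen.  No heading —
and therefore no polygon — exists before the first qualifying relocation.

Vertex placement: for template vertex ``l`` with polar coordinates
``(d_l, theta_l)`` about the reference point, the empirical vertex lies
``d_l`` meters from the fix at bearing ``(theta_l + eta_it - eta*) mod 360``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .io import ID_COL, TIME_COL, X_COL, Y_COL, ConfigurationError, GeometryError

HEADING_COL = "heading"
PART_COL = "part"

#: columns of a heading-state table
HEADING_COLUMNS = [ID_COL, TIME_COL, "anchor_x", "anchor_y", HEADING_COL]


@dataclass
class PlanarModel:
    """Template polygons in a local frame.

    Parameters
    ----------
    reference_point :
        (x, y) of the tracking-device location in the template frame, meters.
    forward_direction_deg :
        The template's forward direction ``eta*``, degrees CCW from +x.
    parts :
        Mapping part name -> ordered vertex ring, an ``(L, 2)`` array with
        ``L >= 3`` (ring not closed; each ring must be simple).
    """

    reference_point: np.ndarray
    forward_direction_deg: float
    parts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.reference_point = np.asarray(self.reference_point, dtype=float)
        if self.reference_point.shape != (2,):
            raise ConfigurationError("reference_point must be an (x, y) pair")
        self.forward_direction_deg = float(self.forward_direction_deg) % 360.0
        if not self.parts:
            raise ConfigurationError("planar model needs at least one part")
        clean = {}
        for name, ring in self.parts.items():
            ring = np.asarray(ring, dtype=float)
            if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 3:
                raise ConfigurationError(
                    f"part {name!r} must be an (L>=3, 2) vertex ring"
                )
            if not Polygon(ring).is_valid:
                raise GeometryError(f"part {name!r} is not a simple ring")
            clean[name] = ring
        self.parts = clean

    @classmethod
    def from_json(cls, path) -> "PlanarModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            reference_point=obj["reference_point"],
            forward_direction_deg=obj["forward_direction_deg"],
            parts={name: np.asarray(v, float) for name, v in obj["parts"].items()},
        )

    def to_json(self, path) -> None:
        obj = {
            "reference_point": self.reference_point.tolist(),
            "forward_direction_deg": self.forward_direction_deg,
            "parts": {name: ring.tolist() for name, ring in self.parts.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def load_model(name_or_path) -> PlanarModel:
    """Load a planar model from a JSON file or a bundled model name.

    Bundled models: ``"calf"`` (three-part calf body approximation) and
    ``"visual_100m_120deg"`` (100-m, 120-degree visual-field triangle).
    """
    name = str(name_or_path)
    bundled = resources.files("polycontact") / "models" / f"{name}.json"
    if bundled.is_file():
        with resources.as_file(bundled) as path:
            return PlanarModel.from_json(path)
    return PlanarModel.from_json(name_or_path)


# ---------------------------------------------------------------------------
# headings
# ---------------------------------------------------------------------------


def estimate_heading(
    track: pd.DataFrame, immobility_threshold: float = 0.0
) -> pd.DataFrame:
    """Estimate per-fix headings and frozen ("pose") positions.

    Returns one row per input fix with columns ``id``, ``time``, ``anchor_x``,
    ``anchor_y`` (the position at which the pose was last updated) and
    ``heading`` (degrees CCW from +x; NaN while undefined).  The pose updates
    only when the displacement from the current anchor is at least the
    immobility threshold and strictly positive — a zero displacement never
    defines a direction, so with threshold 0 every *observed movement*
    updates the pose.
    """
    if immobility_threshold < 0:
        raise ConfigurationError("immobility_threshold must be >= 0")
    x = track[X_COL].to_numpy(float)
    y = track[Y_COL].to_numpy(float)
    anchor_x = np.empty(len(track))
    anchor_y = np.empty(len(track))
    heading = np.full(len(track), np.nan)
    for _, idx in track.groupby(ID_COL, sort=False).indices.items():
        ax, ay, h = x[idx[0]], y[idx[0]], np.nan
        anchor_x[idx[0]], anchor_y[idx[0]] = ax, ay
        for j in idx[1:]:
            dx, dy = x[j] - ax, y[j] - ay
            d = np.hypot(dx, dy)
            if d > 0 and d >= immobility_threshold:
                h = np.degrees(np.arctan2(dy, dx)) % 360.0
                ax, ay = x[j], y[j]
            anchor_x[j], anchor_y[j], heading[j] = ax, ay, h
    out = track[[ID_COL, TIME_COL]].copy()
    out["anchor_x"] = anchor_x
    out["anchor_y"] = anchor_y
    out[HEADING_COL] = heading
    return out


def reposition_reference_point(
    track: pd.DataFrame,
    heading_states: pd.DataFrame,
    offset: tuple[float, float],
) -> pd.DataFrame:
    """Translate fixes a fixed distance away at an angle relative to heading.

    ``offset = (distance_m, angle_deg)``: each fix moves ``distance_m`` meters
    in direction ``heading + angle_deg``.  Fixes with undefined headings are
    omitted.  Applying ``(d, 180)`` and then ``(d, 0)`` recovers the original
    points, since the heading attached to each timestamp is unchanged.
    """
    distance, angle = offset
    merged = track.merge(heading_states[[ID_COL, TIME_COL, HEADING_COL]], on=[ID_COL, TIME_COL])
    merged = merged[merged[HEADING_COL].notna()].reset_index(drop=True)
    theta = np.radians(merged[HEADING_COL].to_numpy() + angle)
    out = merged[[ID_COL, TIME_COL]].copy()
    out[X_COL] = merged[X_COL].to_numpy() + distance * np.cos(theta)
    out[Y_COL] = merged[Y_COL].to_numpy() + distance * np.sin(theta)
    out.attrs.update(track.attrs)
    return out


# ---------------------------------------------------------------------------
# polygon derivation
# ---------------------------------------------------------------------------


def derive_polygons(
    track: pd.DataFrame,
    heading_states: pd.DataFrame,
    model: PlanarModel,
) -> pd.DataFrame:
    """Instantiate a planar model at every fix with a defined heading.

    Returns an oriented-polygon series: one row per (individual, time, part)
    with columns ``id``, ``time``, ``part``, ``heading`` and ``geometry``
    (shapely polygon).  Records with undefined headings (before the first
    qualifying relocation) are skipped.  During immobility spans the pose is
    frozen, so the previous polygons are re-emitted unchanged.
    """
    states = heading_states[heading_states[HEADING_COL].notna()]
    # template offsets about the reference point; each vertex sits at bearing
    # (theta_l + eta - eta*) from the fix, which is the offset vector rotated
    # by (eta - eta*) -- the rotation-matrix form keeps the identity case
    # (eta = eta*) an exact translation
    part_offsets = {
        name: ring - model.reference_point for name, ring in model.parts.items()
    }

    rows = []
    eta_star = model.forward_direction_deg
    for row in states.itertuples():
        eta = row.heading
        loc = np.array([row.anchor_x, row.anchor_y])
        phi = np.radians((eta - eta_star) % 360.0)
        c, s = np.cos(phi), np.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        for name, rel in part_offsets.items():
            verts = loc + rel @ rot.T
            rows.append((row.id, row.time, name, eta, Polygon(verts)))
    return pd.DataFrame(
        rows, columns=[ID_COL, TIME_COL, PART_COL, HEADING_COL, "geometry"]
    )


def build_visual_field_model(height: float, apex_angle: float) -> PlanarModel:
    """Triangular visual-field template with the apex at the tag location.

    The triangle points along the template's forward direction (+y here, so
    ``eta* = 90``); its base sits ``height`` meters ahead with half-width
    ``height * tan(apex_angle / 2)``.  The two base angles are each
    ``(180 - apex_angle) / 2``.
    """
    if not 0 < apex_angle < 180:
        raise ConfigurationError("apex_angle must be in (0, 180) degrees")
    if not height > 0:
        raise ConfigurationError("height must be positive")
    half_width = height * np.tan(np.radians(apex_angle / 2.0))
    ring = np.array([[0.0, 0.0], [half_width, height], [-half_width, height]])
    return PlanarModel(
        reference_point=np.array([0.0, 0.0]),
        forward_direction_deg=90.0,
        parts={"visual": ring},
    )
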