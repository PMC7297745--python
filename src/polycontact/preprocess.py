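"""Cleaning filters and fixed-interval temporal aggregation for RTLS fixes.

The three filters mirror the standard pre-processing sequence for real-time
location data: confinement to the study area, removal of duplicated
(individual, time) reports, and removal of fixes implying impossible movement
speeds.  Each filter returns the filtered table together with a
:class:`FilterReport` so row accounting is explicit and conserving.

``aggregate_time`` regularizes cleaned fixes onto a fixed fix-interval grid by
averaging raw fixes within each interval, producing coordinates representative
of an individual's average location per slot (e.g., per 10-s interval).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .io import ID_COL, TIME_COL, X_COL, Y_COL, ConfigurationError, InputError

logger = logging.getLogger("polycontact")


@dataclass(frozen=True)
class FilterReport:
    rule: str
    rows_removed: int
    rows_kept: int

    @property
    def rows_in(self) -> int:
        return self.rows_removed + self.rows_kept


@dataclass(frozen=True)
class GridSpec:
    """Fixed temporal grid: slots ``[start + k*interval, start + (k+1)*interval)``.

    ``max_fill_gap`` bounds how many empty slots may be filled by carrying an
    individual's last known location forward (0 disables filling).
    """

    interval: int
    start: int
    end: int
    max_fill_gap: int = 0

    def __post_init__(self):
        if self.interval <= 0:
            raise ConfigurationError("grid interval must be positive")
        if self.end <= self.start:
            raise ConfigurationError("grid end must exceed start")
        if (self.end - self.start) % self.interval != 0:
            raise ConfigurationError("grid interval must divide (end - start)")
        if self.max_fill_gap < 0:
            raise ConfigurationError("max_fill_gap must be >= 0")

    @property
    def n_slots(self) -> int:
        return (self.end - self.start) // self.interval

    def times(self) -> np.ndarray:
        return self.start + self.interval * np.arange(self.n_slots)


def _report(rule: str, before: int, after: int) -> FilterReport:
    rep = FilterReport(rule=rule, rows_removed=before - after, rows_kept=after)
    if rep.rows_removed:
        logger.info("%s: removed %d of %d rows", rule, rep.rows_removed, before)
    return rep


def filter_confine(fixes: pd.DataFrame, boundary) -> tuple[pd.DataFrame, FilterReport]:
    """Retain fixes inside or on a confinement boundary polygon.

    Points exactly on the boundary count as inside.  ``boundary`` may be a
    shapely polygon or a vertex sequence.
    """
    if not isinstance(boundary, Polygon):
        vertices = list(boundary)
        if len(vertices) < 3:
            raise ConfigurationError("confinement boundary needs at least 3 vertices")
        boundary = Polygon(vertices)
    points = shapely.points(fixes[X_COL].to_numpy(), fixes[Y_COL].to_numpy())
    keep = shapely.covers(boundary, points)
    out = fixes[keep].reset_index(drop=True)
    out.attrs.update(fixes.attrs)
    return out, _report("confine", len(fixes), len(out))


def filter_duplicates(fixes: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep the first record per (individual, time) in file order."""
    out = fixes.drop_duplicates(subset=[ID_COL, TIME_COL], keep="first").reset_index(
        drop=True
    )
    out.attrs.update(fixes.attrs)
    return out, _report("dup", len(fixes), len(out))


def filter_speed(fixes: pd.DataFrame, max_mps: float) -> tuple[pd.DataFrame, FilterReport]:
    """Drop fixes implying speeds above ``max_mps`` meters/second.

    Single forward pass per individual: a fix is dropped when the speed
    implied from the last *retained* fix exceeds the limit, so one bad fix
    does not cascade into deleting the rest of the track.  The first fix of
    each individual is always retained.
    """
    if not max_mps > 0:
        raise ConfigurationError("max_mps must be positive")
    keep = np.ones(len(fixes), dtype=bool)
    if math.isfinite(max_mps):
        x = fixes[X_COL].to_numpy()
        y = fixes[Y_COL].to_numpy()
        t = fixes[TIME_COL].to_numpy()
        for _, idx in fixes.groupby(ID_COL, sort=False).indices.items():
            anchor = idx[0]
            for j in idx[1:]:
                dt = t[j] - t[anchor]
                dist = math.hypot(x[j] - x[anchor], y[j] - y[anchor])
                if dt <= 0 or dist / dt > max_mps:
                    keep[j] = False
                else:
                    anchor = j
    out = fixes[keep].reset_index(drop=True)
    out.attrs.update(fixes.attrs)
    return out, _report("mps", len(fixes), len(out))


def aggregate_time(fixes: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Average fixes onto the fixed grid; optionally fill short gaps.

    One output record per individual per covered slot, timestamped at the slot
    start, with coordinates equal to the arithmetic mean of the raw fixes in
    that slot.  Empty slots are filled by carrying the last known location
    forward for at most ``grid.max_fill_gap`` consecutive slots; otherwise
    they are absent from the output.
    """
    window = fixes[(fixes[TIME_COL] >= grid.start) & (fixes[TIME_COL] < grid.end)]
    if window.empty:
        raise InputError("no fixes fall within the aggregation window")
    slot = (window[TIME_COL] - grid.start) // grid.interval
    means = (
        window.assign(_slot=slot)
        .groupby([ID_COL, "_slot"], sort=True)[[X_COL, Y_COL]]
        .mean()
        .reset_index()
    )
    rows = []
    for ind, sub in means.groupby(ID_COL, sort=True):
        have = dict(zip(sub["_slot"], zip(sub[X_COL], sub[Y_COL])))
        last = None
        gap = 0
        for k in range(grid.n_slots):
            if k in have:
                last, gap = have[k], 0
            elif last is not None and gap < grid.max_fill_gap:
                gap += 1
            else:
                continue
            rows.append((ind, grid.start + k * grid.interval, last[0], last[1]))
    out = pd.DataFrame(rows, columns=[ID_COL, TIME_COL, X_COL, Y_COL])
    out.attrs.update(fixes.attrs)
    return out
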