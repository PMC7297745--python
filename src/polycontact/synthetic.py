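"""RTLS-like synthetic trajectories with known ground truth.

The generator emulates the salient features of real-time location data for
confined or free-ranging animals: fixes on a fixed 1-10 s interval grid,
correlated-random-walk movement (wrapped-normal turning, reflective arena
boundaries), Gaussian positional error stated as a containment
radius/probability (e.g., 90% of points within 0.5 m), and scripted
ground-truth contact bouts in which a pair of individuals is held at a fixed
separation over a known time span.

Four named scripted scenarios with closed-form expected bouts exercise every
downstream stage: ``converge_pair`` (one point-contact bout of known length),
``parallel_walk`` (contact for the whole run), ``head_to_tail`` (polygon
contacts only in the head-to-posterior pairing) and ``visual_crossing``
(a one-way directed visual edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import AccuracyModel
from .geometry import PlanarModel, build_visual_field_model
from .io import ConfigurationError, make_fixes

SCENARIOS = ("converge_pair", "parallel_walk", "head_to_tail", "visual_crossing")

#: spatial threshold at which each scripted scenario's expected bouts hold
SCENARIO_SPTH = {
    "converge_pair": 0.0,
    "parallel_walk": 0.5,
    "head_to_tail": 0.56,
    "visual_crossing": 0.0,
}


@dataclass(frozen=True)
class ScriptedEvent:
    """Hold a pair of individuals at a fixed separation over [start, end]."""

    pair: tuple[int, int]
    start: int
    end: int
    target_distance: float


@dataclass
class SimConfig:
    n_individuals: int
    arena: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    interval: int
    n_timesteps: int
    step_mean: float
    step_sd: float
    turning_concentration: float  # mean resultant length in [0, 1]
    accuracy: AccuracyModel | None = None
    scripted_events: list[ScriptedEvent] = field(default_factory=list)
    seed: int = 0
    eval_spth: float = 0.0  # threshold defining ground-truth contact flags
    start_time: int = 0
    initial_positions: np.ndarray | None = None
    initial_headings: np.ndarray | None = None

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.arena
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError("arena must have positive area")
        if self.n_timesteps < 2:
            raise ConfigurationError("n_timesteps must be >= 2")
        if not 0 <= self.turning_concentration <= 1:
            raise ConfigurationError("turning_concentration must be in [0, 1]")
        for ev in self.scripted_events:
            if not (xmin <= ev.target_distance <= xmax - xmin):
                raise ConfigurationError("scripted event target outside arena scale")

    def times(self) -> np.ndarray:
        return self.start_time + self.interval * np.arange(self.n_timesteps)


def _turn_sd(concentration: float) -> float:
    # wrapped-normal SD from mean resultant length r: sd = sqrt(-2 ln r)
    if concentration >= 1.0:
        return 0.0
    if concentration <= 0.0:
        return np.inf
    return float(np.sqrt(-2.0 * np.log(concentration)))


def _reflect(value: float, lo: float, hi: float) -> tuple[float, bool]:
    flipped = False
    span = hi - lo
    while not lo <= value <= hi:
        if value < lo:
            value = 2 * lo - value
        else:
            value = 2 * hi - value
        flipped = not flipped
        if span <= 0:
            break
    return value, flipped


def simulate_tracks(cfg: SimConfig):
    """Simulate true and error-contaminated tracks plus ground-truth flags.

    Returns ``(true_fixes, noisy_fixes, truth_flags)``.  ``truth_flags`` has
    one row per (time, unordered pair) with a boolean ``contact`` column
    marking timesteps where the true point separation is at most
    ``cfg.eval_spth``.  With ``accuracy=None`` the noisy table equals the
    true table.
    """
    rng = np.random.default_rng(cfg.seed)
    xmin, ymin, xmax, ymax = cfg.arena
    n, T = cfg.n_individuals, cfg.n_timesteps

    if cfg.initial_positions is not None:
        pos = np.asarray(cfg.initial_positions, dtype=float).copy()
    else:
        pos = np.column_stack(
            (rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n))
        )
    if cfg.initial_headings is not None:
        heading = np.radians(np.asarray(cfg.initial_headings, dtype=float).copy())
    else:
        heading = rng.uniform(0.0, 2 * np.pi, size=n)

    sd = _turn_sd(cfg.turning_concentration)
    coords = np.empty((T, n, 2))
    coords[0] = pos
    for k in range(1, T):
        if np.isinf(sd):
            heading = rng.uniform(0.0, 2 * np.pi, size=n)
        elif sd > 0:
            heading = heading + rng.normal(0.0, sd, size=n)
        steps = np.maximum(rng.normal(cfg.step_mean, cfg.step_sd, size=n), 0.0)
        for i in range(n):
            nx = pos[i, 0] + steps[i] * np.cos(heading[i])
            ny = pos[i, 1] + steps[i] * np.sin(heading[i])
            nx, flip_x = _reflect(nx, xmin, xmax)
            ny, flip_y = _reflect(ny, ymin, ymax)
            if flip_x:
                heading[i] = np.pi - heading[i]
            if flip_y:
                heading[i] = -heading[i]
            pos[i] = (nx, ny)
        coords[k] = pos

    times = cfg.times()
    # scripted events override individual b to sit at the target separation
    for ev in cfg.scripted_events:
        a, b = ev.pair
        in_event = (times >= ev.start) & (times <= ev.end)
        for k in np.nonzero(in_event)[0]:
            offset = coords[k, b] - coords[k, a]
            norm = np.hypot(*offset)
            direction = offset / norm if norm > 0 else np.array([0.0, 1.0])
            coords[k, b] = coords[k, a] + ev.target_distance * direction

    ids = [f"ind{i:02d}" for i in range(n)]
    records = [
        (ids[i], times[k], coords[k, i, 0], coords[k, i, 1])
        for i in range(n)
        for k in range(T)
    ]
    true_fixes = make_fixes(records)

    if cfg.accuracy is None:
        noisy_fixes = true_fixes.copy()
        noisy_fixes.attrs.update(true_fixes.attrs)
    else:
        noise = rng.normal(0.0, cfg.accuracy.sigma, size=(len(true_fixes), 2))
        noisy_fixes = true_fixes.copy()
        noisy_fixes["x"] = noisy_fixes["x"] + noise[:, 0]
        noisy_fixes["y"] = noisy_fixes["y"] + noise[:, 1]

    flag_rows = []
    for k in range(T):
        for i in range(n):
            for j in range(i + 1, n):
                d = float(np.hypot(*(coords[k, j] - coords[k, i])))
                flag_rows.append(
                    (times[k], ids[i], ids[j], d <= cfg.eval_spth)
                )
    truth_flags = pd.DataFrame(
        flag_rows, columns=["time", "id_a", "id_b", "contact"]
    )
    return true_fixes, noisy_fixes, truth_flags


# ---------------------------------------------------------------------------
# scripted scenarios
# ---------------------------------------------------------------------------


def scripted_contact_scenario(name: str) -> SimConfig:
    """Fixed-seed scenario configs whose ground-truth bouts are closed-form."""
    big_arena = (0.0, 0.0, 2000.0, 2000.0)
    if name == "converge_pair":
        return SimConfig(
            n_individuals=2,
            arena=big_arena,
            interval=1,
            n_timesteps=1200,
            step_mean=1.0,
            step_sd=0.0,
            turning_concentration=1.0,
            accuracy=AccuracyModel(delta=0.5, p=0.90),
            scripted_events=[ScriptedEvent(pair=(0, 1), start=200, end=699, target_distance=0.0)],
            seed=2001,
            eval_spth=0.0,
            initial_positions=np.array([[100.0, 100.0], [100.0, 110.0]]),
            initial_headings=np.array([0.0, 0.0]),
        )
    if name == "parallel_walk":
        return SimConfig(
            n_individuals=2,
            arena=big_arena,
            interval=1,
            n_timesteps=600,
            step_mean=1.0,
            step_sd=0.0,
            turning_concentration=1.0,
            seed=2002,
            eval_spth=0.5,
            initial_positions=np.array([[100.0, 100.0], [100.0, 100.4]]),
            initial_headings=np.array([0.0, 0.0]),
        )
    if name == "head_to_tail":
        return SimConfig(
            n_individuals=2,
            arena=big_arena,
            interval=1,
            n_timesteps=500,
            step_mean=1.0,
            step_sd=0.0,
            turning_concentration=1.0,
            seed=2003,
            eval_spth=0.0,
            initial_positions=np.array([[100.0, 100.0], [102.6, 100.0]]),
            initial_headings=np.array([0.0, 0.0]),
        )
    if name == "visual_crossing":
        return SimConfig(
            n_individuals=2,
            arena=big_arena,
            interval=1,
            n_timesteps=300,
            step_mean=1.0,
            step_sd=0.0,
            turning_concentration=1.0,
            seed=2004,
            eval_spth=0.0,
            initial_positions=np.array([[100.0, 100.0], [150.0, 100.0]]),
            initial_headings=np.array([0.0, 0.0]),
        )
    raise ConfigurationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def scenario_model(name: str) -> PlanarModel | None:
    """Planar model paired with a scripted scenario (None for point scenarios)."""
    if name == "head_to_tail":
        # single-file body template: head ahead of the tag, posterior behind
        return PlanarModel(
            reference_point=np.array([0.0, 0.0]),
            forward_direction_deg=0.0,
            parts={
                "head": np.array(
                    [[0.5, -0.1665], [0.833, -0.1665], [0.833, 0.1665], [0.5, 0.1665]]
                ),
                "anterior": np.array(
                    [[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]]
                ),
                "posterior": np.array(
                    [[-1.5, -0.5], [-0.5, -0.5], [-0.5, 0.5], [-1.5, 0.5]]
                ),
            },
        )
    if name == "visual_crossing":
        return build_visual_field_model(height=100.0, apex_angle=120.0)
    return None


def scenario_expected_bouts(name: str) -> pd.DataFrame:
    """Closed-form ground-truth bout tables for the scripted scenarios.

    Times are on each scenario's 1-s grid.  Polygon- and visual-based
    scenarios start at the second timestep (headings, and hence polygons,
    exist only after the first relocation).
    """
    if name == "converge_pair":
        rows = [("ind00", "point", "ind01", "point", False, 200, 699, 500)]
    elif name == "parallel_walk":
        rows = [("ind00", "point", "ind01", "point", False, 0, 599, 600)]
    elif name == "head_to_tail":
        rows = [("ind00", "head", "ind01", "posterior", False, 1, 499, 499)]
    elif name == "visual_crossing":
        rows = [("ind00", "visual", "ind01", "point", True, 1, 299, 299)]
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    return pd.DataFrame(
        rows,
        columns=[
            "id_a",
            "part_a",
            "id_b",
            "part_b",
            "directed",
            "start_time",
            "end_time",
            "n_timesteps",
        ],
    )
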