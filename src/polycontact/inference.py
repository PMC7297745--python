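"""Null models by path randomization, and empirical-vs-null comparisons.

Path randomization destroys temporal synchrony between individuals while
preserving each individual's space use exactly: within each individual the
series is cut into consecutive blocks of ``block_length`` timesteps whose
order is permuted uniformly at random, timestamps staying fixed while the
location blocks move.  Contacts in networks built from such replicates occur
"at random" given where each animal was willing to be.

The randomization stage matters for polygon-based networks: permuting point
fixes *before* polygon derivation also randomizes the headings recomputed
from the permuted relocations, whereas permuting the derived polygon records
*after* derivation keeps the empirical orientations.  Both stages are
supported; the choice is an a-priori analysis decision.

Comparisons: a two-sided permutation Mantel test between contact matrices,
and a chi-squared goodness-of-fit test of observed contact counts against
null-model expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import derive_polygons, estimate_heading
from .io import ID_COL, TIME_COL, ConfigurationError, InputError

SECONDS_PER_DAY = 86_400


@dataclass(frozen=True)
class RandomizationPlan:
    """How to permute trajectories when building null models.

    block_length : number of grid timesteps per shuffled block.
    unit : ``"shuffle_blocks_within_individual"`` permutes all of an
        individual's blocks; ``"shuffle_block_labels_across_days"`` permutes
        blocks only across days while keeping their time-of-day slot.
    stage : ``"before_polygons"`` or ``"after_polygons"``.
    """

    block_length: int
    unit: str = "shuffle_blocks_within_individual"
    stage: str = "before_polygons"
    n_randomizations: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.block_length < 1:
            raise ConfigurationError("block_length must be >= 1")
        if self.n_randomizations < 1:
            raise ConfigurationError("n_randomizations must be >= 1")
        if self.unit not in (
            "shuffle_blocks_within_individual",
            "shuffle_block_labels_across_days",
        ):
            raise ConfigurationError(f"unknown randomization unit {self.unit!r}")
        if self.stage not in ("before_polygons", "after_polygons"):
            raise ConfigurationError(f"unknown randomization stage {self.stage!r}")


def _permute_times(times: np.ndarray, plan: RandomizationPlan, rng) -> dict:
    """Map old time -> new time for one individual under the plan."""
    order = np.argsort(times)
    ordered = times[order]
    if plan.unit == "shuffle_blocks_within_individual":
        if len(ordered) < plan.block_length:
            warnings.warn("series shorter than one block; left unpermuted")
            return dict(zip(ordered, ordered))
        n_blocks = int(np.ceil(len(ordered) / plan.block_length))
        blocks = [
            ordered[i * plan.block_length : (i + 1) * plan.block_length]
            for i in range(n_blocks)
        ]
        perm = rng.permutation(n_blocks)
        source = np.concatenate([blocks[k] for k in perm])
        # i-th timestamp of the ordered grid receives the i-th source location
        return dict(zip(source, ordered))
    # across-days: permute which day's block occupies each within-day slot
    mapping = {}
    frame = pd.DataFrame({"t": ordered, "day": ordered // SECONDS_PER_DAY})
    frame["block"] = frame.groupby("day").cumcount() // plan.block_length
    for _, grp in frame.groupby("block"):
        days = grp["day"].unique()
        perm = rng.permutation(len(days))
        day_map = dict(zip(days, days[perm]))
        by_day = {d: g["t"].to_numpy() for d, g in grp.groupby("day")}
        for d in days:
            src = by_day[day_map[d]]
            dst = by_day[d]
            k = min(len(src), len(dst))
            mapping.update(zip(src[:k], dst[:k]))
            for leftover in dst[k:]:
                mapping[leftover] = leftover
    for t in ordered:
        mapping.setdefault(t, t)
    return mapping


def randomize_paths(table: pd.DataFrame, plan: RandomizationPlan, rng=None) -> pd.DataFrame:
    """One randomized replicate of a fix table or polygon series.

    Within each individual, consecutive blocks of ``block_length`` timesteps
    are re-ordered uniformly at random: the timestamp grid is untouched while
    the locations (or polygon records) attached to those timestamps move as
    blocks.  Each individual's location multiset, record count and timestamp
    set are preserved exactly.
    """
    rng = np.random.default_rng(plan.seed) if rng is None else rng
    out = table.copy()
    new_times = out[TIME_COL].to_numpy().copy()
    for ind, idx in out.groupby(ID_COL, sort=False).indices.items():
        times = np.unique(out[TIME_COL].to_numpy()[idx])
        mapping = _permute_times(times, plan, rng)
        new_times[idx] = [mapping[t] for t in out[TIME_COL].to_numpy()[idx]]
    out[TIME_COL] = new_times
    out = out.sort_values([ID_COL, TIME_COL], kind="stable").reset_index(drop=True)
    out.attrs.update(table.attrs)
    return out


def randomized_polygon_series(
    fixes: pd.DataFrame,
    model,
    plan: RandomizationPlan,
    immobility_threshold: float = 0.0,
    rng=None,
) -> pd.DataFrame:
    """Randomize and derive polygons honoring the plan's stage.

    ``before_polygons``: permute the fixes, then re-estimate headings and
    derive polygons (orientations are therefore randomized too).
    ``after_polygons``: derive polygons from the empirical fixes first, then
    permute the polygon records (empirical orientations are preserved, only
    their timing moves).
    """
    rng = np.random.default_rng(plan.seed) if rng is None else rng
    if plan.stage == "before_polygons":
        shuffled = randomize_paths(fixes, plan, rng)
        states = estimate_heading(shuffled, immobility_threshold)
        return derive_polygons(shuffled, states, model)
    states = estimate_heading(fixes, immobility_threshold)
    series = derive_polygons(fixes, states, model)
    return randomize_paths(series, plan, rng)


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    degenerate: bool = False


def mantel_test(m1, m2, n_perm: int = 10_000, seed=None) -> MantelResult:
    """Two-sided permutation Mantel test between two square matrices.

    ``r`` is the Pearson correlation of the off-diagonal entries; the null
    distribution permutes rows and columns of ``m2`` simultaneously.  The
    p-value includes the observed statistic in the null set:
    ``p = (#{|r_perm| >= |r_obs|} + 1) / (n_perm + 1)``, so ``p`` is never 0
    and equals ``1 / (n_perm + 1)`` when no permutation matches the observed
    correlation.  Matrices with zero off-diagonal variance yield a degenerate
    (NaN) result rather than an arbitrary sign.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConfigurationError("matrices must be square and of equal shape")
    n = a.shape[0]
    mask = ~np.eye(n, dtype=bool)
    va = a[mask]
    if va.std() == 0 or b[mask].std() == 0:
        return MantelResult(r=np.nan, p=np.nan, n_perm=n_perm, degenerate=True)

    def corr_with(perm):
        vb = b[np.ix_(perm, perm)][mask]
        return np.corrcoef(va, vb)[0, 1]

    rng = np.random.default_rng(seed)
    r_obs = corr_with(np.arange(n))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr_with(perm)) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r=float(r_obs), p=(hits + 1) / (n_perm + 1), n_perm=n_perm)


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p: float
    n_pooled: int = 0


def contact_chi2_test(observed, expected) -> Chi2Result:
    """Chi-squared goodness-of-fit of observed contact counts vs null means.

    ``chi2 = sum (O - E)^2 / E`` over cells with ``E > 0``; cells with
    non-positive expectation are pooled into the smallest-expectation valid
    cell before computing the statistic.  ``df = k - 1`` after pooling; the
    p-value is upper-tail.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ConfigurationError("observed and expected must have equal shape")
    valid = exp > 0
    if not valid.any():
        raise InputError("all cells have non-positive expectation")
    n_pooled = int((~valid).sum())
    obs_v = obs[valid].copy()
    exp_v = exp[valid].copy()
    if n_pooled:
        sink = int(np.argmin(exp_v))
        obs_v[sink] += obs[~valid].sum()
        exp_v[sink] += exp[~valid].sum()
    chi2 = float(((obs_v - exp_v) ** 2 / exp_v).sum())
    df = len(exp_v) - 1
    if df < 1:
        raise InputError("fewer than two cells remain after pooling")
    return Chi2Result(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), n_pooled=n_pooled)
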