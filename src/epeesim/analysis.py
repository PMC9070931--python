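"""Career and tournament statistics, and calibration of the talent strength.

The headline statistics mirror what can be measured on real federation
rankings: year-over-year rank-transition matrices between rank groups,
normalized total-points curves, 2-D kernel densities of initial position vs.
final placement within single events, and (simulation-only) talent as a
function of final rank. Calibration estimates the talent strength ``a`` by
grid search, minimizing the mean squared error between simulated and
reference statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .config import SimulationConfig
from .season import RunOutput, SimulationOutput, run_simulation

__all__ = [
    "RankBins",
    "TransitionMatrix",
    "PlacementDensity",
    "CalibrationResult",
    "transition_matrix",
    "normalized_points_curve",
    "placement_density",
    "talent_vs_rank",
    "mse",
    "calibrate_a",
    "simulated_transition",
]

logger = logging.getLogger(__name__)

_DEFAULT_EDGES = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class RankBins:
    """Contiguous inclusive rank intervals covering 1..max_rank.

    ``edges`` are the interior upper bounds; the last bin is open-ended up
    to the population size. Defaults follow the points-scale band
    boundaries (16/32/64/128/256).
    """

    edges: tuple[int, ...] = _DEFAULT_EDGES

    def __post_init__(self) -> None:
        if not self.edges or list(self.edges) != sorted(set(self.edges)):
            raise ValueError("bin edges must be strictly increasing")
        if self.edges[0] < 1:
            raise ValueError("first bin upper bound must be >= 1")

    def for_max_rank(self, max_rank: int) -> "RankBins":
        """Drop edges at or beyond ``max_rank`` so the last bin is non-empty."""
        kept = tuple(e for e in self.edges if e < max_rank)
        return RankBins(edges=kept) if kept else RankBins(edges=(max_rank,))

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def bin_of(self, ranks: np.ndarray) -> np.ndarray:
        """Bin index for each 1-based rank."""
        return np.searchsorted(np.asarray(self.edges), ranks, side="left")

    def labels(self, max_rank: int | None = None) -> list[str]:
        lows = (1,) + tuple(e + 1 for e in self.edges)
        highs = self.edges + (max_rank,)
        return [f"{lo}-{hi if hi is not None else 'end'}"
                for lo, hi in zip(lows, highs)]

    @classmethod
    def parse_label(cls, label: str) -> tuple[int, int | None]:
        lo, hi = label.split("-")
        return int(lo), (None if hi == "end" else int(hi))


@dataclass
class TransitionMatrix:
    """Rank-group transition probabilities between consecutive seasons.

    ``direction == "forward"``: row i gives P(next-season bin | this-season
    bin i). ``direction == "backward"``: row j gives P(previous-season bin |
    next-season bin j) — i.e. where the fencers who *end* a season in bin j
    started it. ``mean``/``sd`` are across runs; ``pooled`` normalizes the
    counts pooled over all runs and season pairs.
    """

    bins: RankBins
    direction: str
    mean: np.ndarray
    sd: np.ndarray
    pooled: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        labels = self.bins.labels()
        rows = []
        for i, from_label in enumerate(labels):
            for j, to_label in enumerate(labels):
                rows.append({
                    "direction": self.direction,
                    "from_bin": from_label,
                    "to_bin": to_label,
                    "probability": self.mean[i, j],
                    "sd": self.sd[i, j],
                    "pooled": self.pooled[i, j],
                })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlacementDensity:
    """2-D Gaussian kernel density of (initial position, final placement),
    normalized so the peak equals 1."""

    x: np.ndarray            # initial-position grid
    y: np.ndarray            # final-placement grid
    density: np.ndarray      # shape (len(y), len(x))
    conditioning: str
    n_pairs: int


@dataclass
class CalibrationResult:
    a_star: float
    table: pd.DataFrame      # columns: a, mse
    statistic: str


def _season_pairs(ranks: np.ndarray, burn_in: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Consecutive-season (start, end) rank pairs, excluding the burn-in.

    A pair (s, s+1) reads: a fencer *starts* season s+1 with the rank they
    held at the end of season s; only pairs with both seasons after the
    burn-in are used.
    """
    n_seasons = ranks.shape[0]
    return [(ranks[s], ranks[s + 1]) for s in range(burn_in, n_seasons - 1)]


def transition_matrix(rankings_by_run: Sequence[np.ndarray] | SimulationOutput,
                      bins: RankBins | None = None,
                      direction: Literal["forward", "backward"] = "backward",
                      burn_in: int = 1) -> TransitionMatrix:
    """Empirical rank-group transition matrix between consecutive seasons.

    ``rankings_by_run``: per run, an (n_seasons, n_athletes) array of
    end-of-season ranks (or a ``SimulationOutput``). Counts are accumulated
    over all consecutive-season pairs after the burn-in; conditioning rows
    are normalized per run (mean/sd across runs) and over the pooled counts.
    """
    if isinstance(rankings_by_run, SimulationOutput):
        rankings_by_run = [r.season_end_ranks for r in rankings_by_run.runs]
    if not len(rankings_by_run):
        raise ValueError("need at least one run")
    max_rank = int(max(r.max() for r in rankings_by_run))
    bins = (bins or RankBins()).for_max_rank(max_rank)
    k = bins.n_bins

    per_run = []
    total_counts = np.zeros((k, k))
    for ranks in rankings_by_run:
        if ranks.shape[0] < burn_in + 2:
            raise ValueError(
                "need at least two post-burn-in seasons for transitions"
            )
        counts = np.zeros((k, k))
        for start, end in _season_pairs(ranks, burn_in):
            i = bins.bin_of(start)
            j = bins.bin_of(end)
            np.add.at(counts, (i, j), 1)
        total_counts += counts
        per_run.append(_normalize(counts, direction))
    stack = np.stack(per_run)
    return TransitionMatrix(
        bins=bins,
        direction=direction,
        mean=np.nanmean(stack, axis=0),
        sd=np.nanstd(stack, axis=0, ddof=0) if len(per_run) > 1
        else np.zeros((k, k)),
        pooled=_normalize(total_counts, direction),
        counts=total_counts,
    )


def _normalize(counts: np.ndarray, direction: str) -> np.ndarray:
    """Row-stochastic conditional matrix; conditioning bin indexes the rows."""
    if direction == "forward":
        cond = counts
    elif direction == "backward":
        cond = counts.T
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return cond / cond.sum(axis=1, keepdims=True)


def normalized_points_curve(output: SimulationOutput | Sequence[np.ndarray],
                            burn_in: int = 1) -> np.ndarray:
    """Mean total points per ranking position, normalized to the maximum.

    Averages the descending-sorted season totals across all post-burn-in
    seasons and runs, then divides by the value at position 1.
    """
    if isinstance(output, SimulationOutput):
        points_by_run = [r.season_end_points for r in output.runs]
    else:
        points_by_run = list(output)
    curves = []
    for pts in points_by_run:
        for s in range(burn_in, pts.shape[0]):
            curves.append(np.sort(pts[s])[::-1])
    if not curves:
        raise ValueError("no post-burn-in seasons available")
    mean_curve = np.mean(curves, axis=0)
    top = mean_curve[0]
    return mean_curve / top if top > 0 else mean_curve


def placement_density(event_results: Sequence[tuple[np.ndarray, np.ndarray]] | SimulationOutput,
                      conditioning: Literal["initial-top-16", "final-top-16"] = "final-top-16",
                      top: int = 16,
                      bandwidth: float | str | None = None,
                      grid_size: int = 100) -> PlacementDensity:
    """Kernel density of initial position vs. final placement within events.

    ``event_results``: per event, a pair of aligned arrays (initial
    positions, final placements), or a ``SimulationOutput`` (all events
    after the burn-in season). Pairs are pooled, conditioned on the chosen
    side being within the ``top`` positions, smoothed with a 2-D Gaussian
    kernel (Silverman bandwidth unless overridden), and normalized to peak 1.
    """
    if isinstance(event_results, SimulationOutput):
        pairs = []
        for run in event_results.runs:
            for ev in run.events:
                if ev.season >= 1:
                    pairs.append((np.arange(1, len(ev.entrants) + 1),
                                  ev.placements))
        event_results = pairs
    init = np.concatenate([np.asarray(p[0], float) for p in event_results])
    fin = np.concatenate([np.asarray(p[1], float) for p in event_results])
    if conditioning == "initial-top-16":
        mask = init <= top
    elif conditioning == "final-top-16":
        mask = fin <= top
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    init, fin = init[mask], fin[mask]
    if len(init) == 0:
        raise ValueError("no event pairs satisfy the conditioning")
    data = np.vstack([init, fin])
    try:
        kde = gaussian_kde(data, bw_method=bandwidth)
    except np.linalg.LinAlgError:
        # Degenerate (e.g. perfectly rank-preserving) samples have a singular
        # covariance; a microscopic deterministic jitter restores rank.
        jitter = np.random.default_rng(0).normal(0, 1e-6, size=data.shape)
        kde = gaussian_kde(data + jitter, bw_method=bandwidth)
    x = np.linspace(init.min() - 1, init.max() + 1, grid_size)
    y = np.linspace(fin.min() - 1, fin.max() + 1, grid_size)
    xx, yy = np.meshgrid(x, y)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    peak = dens.max()
    if peak > 0:
        dens = dens / peak
    return PlacementDensity(x=x, y=y, density=dens, conditioning=conditioning,
                            n_pairs=len(init))


def talent_vs_rank(output: SimulationOutput,
                   season: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD (across runs) of talent at each final-ranking position.

    Uses the requested season's end-of-season ranking (default: the last).
    """
    rows = []
    for run in output.runs:
        ranks = run.season_end_ranks[season]
        by_pos = np.empty(run.n_athletes)
        by_pos[ranks - 1] = run.talents
        rows.append(by_pos)
    stack = np.stack(rows)
    sd = stack.std(axis=0, ddof=0) if len(rows) > 1 else np.zeros(stack.shape[1])
    return stack.mean(axis=0), sd


def mse(simulated: np.ndarray, reference: np.ndarray) -> float:
    """Mean squared error over cells defined (finite) in both statistics."""
    a = np.asarray(simulated, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"statistic shapes differ: {a.shape} vs {b.shape}")
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        raise ValueError("no overlapping defined cells between statistics")
    n_missing = a.size - int(valid.sum())
    if n_missing:
        logger.debug("mse: excluded %d undefined cells", n_missing)
    return float(np.mean((a[valid] - b[valid]) ** 2))


# --------------------------------------------------------------------------- #
# Calibration
# --------------------------------------------------------------------------- #


def simulated_transition(config: SimulationConfig, a: float, seed: int,
                         bins: RankBins | None = None,
                         direction: str = "backward",
                         n_runs: Optional[int] = None) -> TransitionMatrix:
    """Run the simulator at talent strength ``a`` and return its transition
    statistic (run-averaged)."""
    cfg = config.replace(talent_strength=float(a))
    out = run_simulation(cfg, seed=seed, n_runs=n_runs)
    return transition_matrix(out, bins=bins, direction=direction)  # type: ignore[arg-type]


def calibrate_a(reference: TransitionMatrix | np.ndarray,
                grid: Sequence[float],
                config: SimulationConfig,
                seed: int = 0,
                statistic: Literal["transition", "points"] = "transition",
                direction: str = "backward",
                bins: RankBins | None = None,
                n_runs: Optional[int] = None) -> CalibrationResult:
    """Grid-search the talent strength by MSE against a reference statistic.

    Every grid value is simulated with the same root seed (common random
    numbers, which reduces the variance of MSE differences across the
    grid); ties go to the smaller ``a``.
    """
    grid = sorted(float(a) for a in grid)
    if not grid:
        raise ValueError("calibration grid must be non-empty")
    if isinstance(reference, TransitionMatrix):
        if bins is None:
            bins = reference.bins
        ref_stat = reference.mean
    else:
        ref_stat = np.asarray(reference, dtype=float)

    rows = []
    for a in grid:
        if statistic == "transition":
            sim = simulated_transition(config, a, seed, bins=bins,
                                       direction=direction, n_runs=n_runs)
            value = mse(sim.mean, ref_stat)
        elif statistic == "points":
            cfg = config.replace(talent_strength=a)
            out = run_simulation(cfg, seed=seed, n_runs=n_runs)
            curve = normalized_points_curve(out)
            value = mse(curve, ref_stat)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        rows.append({"a": a, "mse": value})
        logger.info("calibration: a=%.3f mse=%.6g", a, value)
    table = pd.DataFrame(rows)
    best = int(np.argmin(table["mse"].to_numpy()))
    ties = np.flatnonzero(np.isclose(table["mse"], table["mse"].iloc[best]))
    if len(ties) > 1:
        logger.info("calibration: %d tied minima, keeping smallest a", len(ties))
    return CalibrationResult(a_star=float(table["a"].iloc[best]), table=table,
                             statistic=statistic)
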