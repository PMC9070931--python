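"""Athlete community: talent sampling and initial-ranking setup.

Talent is an intrinsic, per-agent constant drawn from a Gaussian with mean
0.6 and SD 0.1, restricted to (0, 1] by rejection resampling (re-drawing out
of range values rather than clipping, so no probability mass piles up at the
bounds). The initial ranking is a uniformly random permutation; points start
at zero and are earned event by event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig

__all__ = ["Fencer", "Population", "sample_talents", "init_population"]


@dataclass(frozen=True)
class Fencer:
    """Read-only view of one agent in the population."""

    id: int
    talent: float
    slot_points: np.ndarray
    rank: int

    @property
    def total_points(self) -> float:
        return float(self.slot_points.sum())


class Population:
    """The community of fencers for one simulation run.

    State is stored columnar: ``talents[i]`` is fencer ``i``'s talent,
    ``slot_points[i, e]`` the points currently counted for event slot ``e``
    (the rolling ranking), and ``ranks[i]`` the current rank (1 = best).
    """

    def __init__(self, talents: np.ndarray, n_event_slots: int,
                 ranks: np.ndarray) -> None:
        talents = np.asarray(talents, dtype=float)
        ranks = np.asarray(ranks, dtype=int)
        n = len(talents)
        if len(ranks) != n:
            raise ValueError("talents and ranks must have equal length")
        if sorted(ranks.tolist()) != list(range(1, n + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        self.talents = talents
        self.slot_points = np.zeros((n, n_event_slots), dtype=float)
        self.ranks = ranks

    @property
    def n(self) -> int:
        return len(self.talents)

    @property
    def total_points(self) -> np.ndarray:
        return self.slot_points.sum(axis=1)

    def fencer(self, i: int) -> Fencer:
        return Fencer(id=i, talent=float(self.talents[i]),
                      slot_points=self.slot_points[i].copy(),
                      rank=int(self.ranks[i]))

    def ids_by_rank(self) -> np.ndarray:
        """Fencer ids ordered best-to-worst by current rank."""
        return np.argsort(self.ranks, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fencer_id": np.arange(self.n),
                "talent": self.talents,
                "rank": self.ranks,
                "total_points": self.total_points,
            }
        )


def sample_talents(n: int, mean: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` talents from N(mean, sd) truncated to (0, 1] by rejection.

    ``sd == 0`` degenerates to the constant ``mean`` (which must itself lie
    in (0, 1]).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if not 0.0 < mean <= 1.0:
        raise ValueError(f"mean must lie in (0, 1], got {mean}")
    if sd == 0:
        return np.full(n, mean, dtype=float)
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=n - filled)
        keep = draw[(draw > 0.0) & (draw <= 1.0)]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def init_population(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Population with sampled talents, zero points, random initial ranking."""
    talents = sample_talents(config.n_athletes, config.talent_mean,
                             config.talent_sd, rng)
    ranks = rng.permutation(config.n_athletes) + 1
    return Population(talents, config.n_tournaments_per_season, ranks)
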