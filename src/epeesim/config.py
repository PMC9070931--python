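"""Simulation configuration, the FIE-style points scale, and participation models.

The defaults reproduce the Junior Men setup used throughout the package:
7 seasons (the first a burn-in "trial" season), 8 World-Cup-like events per
season, 600 athletes, talent ~ N(0.6, 0.1) truncated to (0, 1], and a single
free parameter ``talent_strength`` (a) weighting talent against chance in
every touch.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PointsScale",
    "ParticipationModel",
    "SimulationConfig",
    "men_config",
    "women_config",
]


# --------------------------------------------------------------------------- #
# Points scale
# --------------------------------------------------------------------------- #

# (first place in band, last place in band or None for open-ended, points)
_FIE_BANDS: tuple[tuple[int, int | None, float], ...] = (
    (1, 1, 32.0),
    (2, 2, 26.0),
    (3, 4, 20.0),      # 3rd ex aequo: both semi-final losers
    (5, 8, 14.0),
    (9, 16, 8.0),
    (17, 32, 4.0),
    (33, 64, 2.0),
    (65, 96, 1.0),
    (97, 128, 0.5),
    (129, 256, 0.25),
    (257, None, 0.1),
)


@dataclass(frozen=True)
class PointsScale:
    """Placement-band -> ranking-points table (official FIE scale by default).

    Bands are inclusive, contiguous from place 1 upward, with strictly
    decreasing points; the last band is open-ended.
    """

    bands: tuple[tuple[int, int | None, float], ...] = _FIE_BANDS

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("points scale needs at least one band")
        expect_lo = 1
        prev_pts = math.inf
        for i, (lo, hi, pts) in enumerate(self.bands):
            if lo != expect_lo:
                raise ValueError(
                    f"points scale bands must be contiguous from place 1: "
                    f"band {i} starts at {lo}, expected {expect_lo}"
                )
            if hi is None:
                if i != len(self.bands) - 1:
                    raise ValueError("only the last band may be open-ended")
            else:
                if hi < lo:
                    raise ValueError(f"band {i} has upper bound {hi} < lower {lo}")
                expect_lo = hi + 1
            if pts >= prev_pts:
                raise ValueError("points must strictly decrease across bands")
            prev_pts = pts

    def points_for(self, placement: int) -> float:
        """Points awarded for a final placement (1 = winner)."""
        if placement < 1:
            raise ValueError(f"placement must be >= 1, got {placement}")
        for lo, hi, pts in self.bands:
            if hi is None or placement <= hi:
                if placement >= lo:
                    return pts
        raise AssertionError("contiguous bands cannot miss a placement")

    def to_list(self) -> list[list[Any]]:
        return [[lo, hi, pts] for lo, hi, pts in self.bands]

    @classmethod
    def from_list(cls, rows: Iterable[Sequence[Any]]) -> "PointsScale":
        bands = tuple(
            (int(lo), None if hi is None else int(hi), float(pts))
            for lo, hi, pts in rows
        )
        return cls(bands=bands)


# --------------------------------------------------------------------------- #
# Participation model
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class ParticipationModel:
    """Rank-stratified distribution of the number of events attended per season.

    ``strata`` are increasing upper quantile bounds of the current ranking
    (the last must be 1.0); ``distributions[s][k]`` is the probability that a
    fencer in stratum ``s`` attends exactly ``k`` of the season's events.

    The default emulates real World-Cup attendance: top-ranked fencers travel
    to most events, the bottom of the ranking to only a couple, which makes
    the typical event field a fraction of the whole community.
    """

    strata: tuple[float, ...]
    distributions: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if len(self.strata) != len(self.distributions):
            raise ValueError("one distribution per stratum required")
        if not self.strata:
            raise ValueError("at least one stratum required")
        prev = 0.0
        for q in self.strata:
            if not prev < q <= 1.0:
                raise ValueError(
                    f"strata must be increasing quantiles in (0, 1], got {self.strata}"
                )
            prev = q
        if self.strata[-1] != 1.0:
            raise ValueError("last stratum bound must be 1.0 so all ranks are covered")
        n_k = len(self.distributions[0])
        for s, dist in enumerate(self.distributions):
            if len(dist) != n_k:
                raise ValueError("all strata must share the same event-count support")
            arr = np.asarray(dist, dtype=float)
            if (arr < 0).any() or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"stratum {s} distribution must be a probability vector")

    @property
    def n_events(self) -> int:
        return len(self.distributions[0]) - 1

    def stratum_of(self, rank: int, n_athletes: int) -> int:
        """Stratum index for a 1-based rank in a population of ``n_athletes``."""
        q = rank / n_athletes
        for s, bound in enumerate(self.strata):
            if q <= bound + 1e-12:
                return s
        return len(self.strata) - 1

    def sample_counts(self, ranks: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw the number of events attended for every fencer (by rank)."""
        n = len(ranks)
        counts = np.empty(n, dtype=int)
        support = np.arange(self.n_events + 1)
        strata_idx = np.array([self.stratum_of(int(r), n) for r in ranks])
        for s, dist in enumerate(self.distributions):
            mask = strata_idx == s
            if mask.any():
                counts[mask] = rng.choice(support, size=int(mask.sum()), p=np.asarray(dist))
        return counts

    @classmethod
    def full(cls, n_events: int) -> "ParticipationModel":
        """Everyone attends every event (used for idealized experiments)."""
        dist = tuple(0.0 for _ in range(n_events)) + (1.0,)
        return cls(strata=(1.0,), distributions=(dist,))

    @classmethod
    def default(cls, n_events: int = 8) -> "ParticipationModel":
        """Monotone synthetic attendance: binomial event counts with
        attendance probability decreasing down the ranking (0.7 / 0.5 / 0.35 /
        0.2 for the top 10%, 10-30%, 30-60% and bottom 40%)."""
        from scipy.stats import binom

        strata = (0.10, 0.30, 0.60, 1.00)
        probs = (0.70, 0.50, 0.35, 0.20)
        support = np.arange(n_events + 1)
        dists = tuple(
            tuple(binom.pmf(support, n_events, p).tolist()) for p in probs
        )
        return cls(strata=strata, distributions=dists)

    def to_dict(self) -> dict[str, Any]:
        return {
            "strata": list(self.strata),
            "distributions": [list(d) for d in self.distributions],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParticipationModel":
        return cls(
            strata=tuple(float(x) for x in d["strata"]),
            distributions=tuple(tuple(float(p) for p in row) for row in d["distributions"]),
        )

    def to_frame(self):
        """Long-form table: stratum_bound (upper quantile), k, probability."""
        import pandas as pd

        rows = [
            {"stratum_bound": bound, "k": k, "probability": p}
            for bound, dist in zip(self.strata, self.distributions)
            for k, p in enumerate(dist)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame) -> "ParticipationModel":
        strata = tuple(sorted(frame["stratum_bound"].unique()))
        dists = []
        for bound in strata:
            sub = frame[frame["stratum_bound"] == bound].sort_values("k")
            dists.append(tuple(float(p) for p in sub["probability"]))
        return cls(strata=tuple(float(b) for b in strata),
                   distributions=tuple(dists))


# --------------------------------------------------------------------------- #
# Simulation configuration
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter set for a simulation run (defaults: Junior Men setup)."""

    n_seasons: int = 7
    n_tournaments_per_season: int = 8
    n_athletes: int = 600
    talent_mean: float = 0.6
    talent_sd: float = 0.1
    talent_strength: float = 0.45
    mean_chance_low: float = 0.3
    mean_chance_high: float = 0.7
    chance_halfwidth: float = 0.3
    touch_interval_min: float = 2.0
    touch_interval_max: float = 60.0
    pool_size: int = 6
    pool_target_hits: int = 5
    pool_duration: float = 180.0
    de_target_hits: int = 15
    de_n_periods: int = 3
    de_period_duration: float = 180.0
    priority_duration: float = 60.0
    qualified_fraction: float = 0.7
    double_prefactor: float = 0.4
    n_runs: int = 10
    rng_seed: int = 0
    # "score": a double at simultaneous match point stands and the bout goes
    # to priority; "annul": doubles are not scored when both fencers are one
    # hit from the target.
    double_at_match_point: str = "score"
    # "expire": skipping an event zeroes last season's points in that slot;
    # "keep": they stand until replaced.
    skipped_event_points: str = "expire"
    points_scale: PointsScale = field(default_factory=PointsScale)
    participation_model: ParticipationModel | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self
        for name in ("n_seasons", "n_tournaments_per_season", "n_athletes", "n_runs",
                     "pool_target_hits", "de_target_hits", "de_n_periods"):
            if getattr(c, name) < 1:
                raise ValueError(f"{name} must be a positive count, got {getattr(c, name)}")
        if not 0.0 <= c.talent_strength <= 1.0:
            raise ValueError(
                f"talent_strength must lie in [0, 1], got {c.talent_strength}"
            )
        if not 0.0 < c.talent_mean <= 1.0:
            raise ValueError(f"talent_mean must lie in (0, 1], got {c.talent_mean}")
        if c.talent_sd < 0.0:
            raise ValueError(f"talent_sd must be >= 0, got {c.talent_sd}")
        if not (0.0 <= c.mean_chance_low <= c.mean_chance_high <= 1.0):
            raise ValueError(
                "mean_chance bounds must satisfy 0 <= low <= high <= 1, got "
                f"[{c.mean_chance_low}, {c.mean_chance_high}]"
            )
        if c.chance_halfwidth < 0.0:
            raise ValueError(f"chance_halfwidth must be >= 0, got {c.chance_halfwidth}")
        if c.mean_chance_low - c.chance_halfwidth < -1e-12 or \
           c.mean_chance_high + c.chance_halfwidth > 1.0 + 1e-12:
            raise ValueError(
                "per-touch chance support must stay inside [0, 1]: "
                f"mean chance in [{c.mean_chance_low}, {c.mean_chance_high}] "
                f"with halfwidth {c.chance_halfwidth} escapes it"
            )
        if not (0.0 < c.touch_interval_min <= c.touch_interval_max):
            raise ValueError("touch intervals must satisfy 0 < min <= max")
        if c.pool_size < 2:
            raise ValueError(f"pool_size must be >= 2, got {c.pool_size}")
        if not 0.0 < c.qualified_fraction <= 1.0:
            raise ValueError(
                f"qualified_fraction must lie in (0, 1], got {c.qualified_fraction}"
            )
        if not 0.0 <= c.double_prefactor <= 1.0:
            raise ValueError(f"double_prefactor must lie in [0, 1], got {c.double_prefactor}")
        if c.pool_duration <= 0 or c.de_period_duration <= 0 or c.priority_duration <= 0:
            raise ValueError("bout durations must be positive")
        if c.double_at_match_point not in ("score", "annul"):
            raise ValueError("double_at_match_point must be 'score' or 'annul'")
        if c.skipped_event_points not in ("expire", "keep"):
            raise ValueError("skipped_event_points must be 'expire' or 'keep'")
        if c.participation_model is not None and \
                c.participation_model.n_events != c.n_tournaments_per_season:
            raise ValueError(
                "participation model event support must match n_tournaments_per_season"
            )

    def get_participation_model(self) -> ParticipationModel:
        if self.participation_model is not None:
            return self.participation_model
        return ParticipationModel.default(self.n_tournaments_per_season)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, PointsScale):
                d[f.name] = v.to_list()
            elif isinstance(v, ParticipationModel):
                d[f.name] = v.to_dict()
            else:
                d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(d)
        if "points_scale" in kwargs and kwargs["points_scale"] is not None:
            if not isinstance(kwargs["points_scale"], PointsScale):
                kwargs["points_scale"] = PointsScale.from_list(kwargs["points_scale"])
        if "participation_model" in kwargs and kwargs["participation_model"] is not None:
            if not isinstance(kwargs["participation_model"], ParticipationModel):
                kwargs["participation_model"] = ParticipationModel.from_dict(
                    kwargs["participation_model"]
                )
        return cls(**kwargs)

    def replace(self, **changes: Any) -> "SimulationConfig":
        return replace(self, **changes)


def men_config(**overrides: Any) -> SimulationConfig:
    """Junior Men defaults: 600 athletes, 7 seasons, 8 events."""
    return SimulationConfig(**overrides)


def women_config(**overrides: Any) -> SimulationConfig:
    """Junior Women defaults: as men but a community of 500 athletes."""
    overrides.setdefault("n_athletes", 500)
    return SimulationConfig(**overrides)
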