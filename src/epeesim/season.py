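"""Multi-season careers: participation, the rolling ranking, and full runs.

Each season every fencer draws the number of events to attend from a
rank-stratified participation model, then attends a uniformly random subset
of the season's event slots. The ranking is rolling, not cumulative: a new
result replaces (and a skipped event expires) last year's result in the same
event slot. The first simulated season is a burn-in "trial" stage that only
seeds the rolling ranking; analyses exclude it by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ParticipationModel, SimulationConfig
from .population import Population, init_population
from .tournament import TournamentResult, run_tournament

__all__ = [
    "EventRecord",
    "RunOutput",
    "SimulationOutput",
    "plan_participation",
    "select_entrants",
    "update_rolling_ranking",
    "run_single",
    "run_simulation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EventRecord:
    """Slim per-event summary kept for whole-run analyses."""

    season: int
    event_index: int
    entrants: np.ndarray            # ids in initial-position order
    placements: np.ndarray          # aligned with entrants
    points: np.ndarray              # aligned with entrants


@dataclass
class RunOutput:
    """One independent replicate of the whole multi-season simulation."""

    talents: np.ndarray                       # (n_athletes,)
    season_end_ranks: np.ndarray              # (n_seasons, n_athletes)
    season_end_points: np.ndarray             # (n_seasons, n_athletes)
    events: list[EventRecord] = field(default_factory=list)
    skipped_events: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_seasons(self) -> int:
        return self.season_end_ranks.shape[0]

    @property
    def n_athletes(self) -> int:
        return self.season_end_ranks.shape[1]

    def rankings_frame(self, run: int = 0) -> pd.DataFrame:
        rows = []
        for s in range(self.n_seasons):
            rows.append(pd.DataFrame({
                "run": run,
                "season": s,
                "fencer_id": np.arange(self.n_athletes),
                "rank": self.season_end_ranks[s],
                "total_points": self.season_end_points[s],
                "talent": self.talents,
            }))
        return pd.concat(rows, ignore_index=True)

    def events_frame(self, run: int = 0) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            rows.append(pd.DataFrame({
                "run": run,
                "season": ev.season,
                "event": ev.event_index,
                "fencer_id": ev.entrants,
                "initial_position": np.arange(1, len(ev.entrants) + 1),
                "final_placement": ev.placements,
                "points": ev.points,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SimulationOutput:
    """All replicates of a simulation plus the configuration that made them."""

    config: SimulationConfig
    root_seed: Optional[int]
    runs: list[RunOutput]

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def rankings_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.rankings_frame(i) for i, r in enumerate(self.runs)],
            ignore_index=True,
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.events_frame(i) for i, r in enumerate(self.runs)],
            ignore_index=True,
        )


# --------------------------------------------------------------------------- #
# Season mechanics
# --------------------------------------------------------------------------- #


def plan_participation(population: Population, model: ParticipationModel,
                       rng: np.random.Generator) -> np.ndarray:
    """Boolean attendance matrix (n_athletes, n_events) for one season.

    Each fencer draws an event count k from their rank stratum's
    distribution, then attends k uniformly random event slots.
    """
    n_events = model.n_events
    counts = model.sample_counts(population.ranks, rng)
    plan = np.zeros((population.n, n_events), dtype=bool)
    for i, k in enumerate(counts):
        if k:
            plan[i, rng.choice(n_events, size=int(k), replace=False)] = True
    return plan


def select_entrants(event_index: int, plan: np.ndarray,
                    population: Population,
                    pool_size: int = 6) -> np.ndarray:
    """Entrant ids for one event, best-to-worst by current rank, trimmed to a
    multiple of the pool size by deferring the lowest-ranked surplus.

    Returns an empty array (the event is skipped) when fewer than
    ``pool_size`` fencers planned to attend.
    """
    planned = np.flatnonzero(plan[:, event_index])
    if len(planned) < pool_size:
        logger.warning(
            "event %d skipped: only %d entrants planned (need >= %d)",
            event_index, len(planned), pool_size,
        )
        return np.empty(0, dtype=int)
    order = np.argsort(population.ranks[planned], kind="stable")
    entrants = planned[order]
    surplus = len(entrants) % pool_size
    if surplus:
        entrants = entrants[:-surplus]
    return entrants


def update_rolling_ranking(population: Population, event_index: int,
                           result: TournamentResult,
                           rng: np.random.Generator,
                           skipped_event_points: str = "expire") -> None:
    """Write an event's points into its ranking slot and re-rank.

    Competitors' slot values are replaced by this event's points;
    non-competitors' slots expire to zero (default) or are kept, per
    ``skipped_event_points``. Ties in total points are broken by lot, which
    also shuffles the zero-point tail.
    """
    slot = population.slot_points[:, event_index]
    if skipped_event_points == "expire":
        slot[:] = 0.0
    for fid, pts in result.points.items():
        slot[fid] = pts
    rerank(population, rng)


def rerank(population: Population, rng: np.random.Generator) -> None:
    """Sort descending by total points, random lots breaking ties."""
    totals = population.total_points
    lots = rng.permutation(population.n)
    order = np.lexsort((lots, -totals))
    ranks = np.empty(population.n, dtype=int)
    ranks[order] = np.arange(1, population.n + 1)
    population.ranks = ranks


# --------------------------------------------------------------------------- #
# Full runs
# --------------------------------------------------------------------------- #


def run_single(config: SimulationConfig,
               seed_seq: np.random.SeedSequence) -> RunOutput:
    """One replicate: init the community, then N_S seasons of N_T events.

    Sub-streams are split hierarchically from ``seed_seq`` (one for the
    population, one for season-level draws, one per tournament) so replicates
    are reproducible in isolation.
    """
    pop_ss, season_ss = seed_seq.spawn(2)
    rng_pop = np.random.default_rng(pop_ss)
    rng_season = np.random.default_rng(season_ss)
    population = init_population(config, rng_pop)
    model = config.get_participation_model()

    n_s, n_t = config.n_seasons, config.n_tournaments_per_season
    season_end_ranks = np.empty((n_s, population.n), dtype=int)
    season_end_points = np.empty((n_s, population.n), dtype=float)
    events: list[EventRecord] = []
    skipped: list[tuple[int, int]] = []

    for season in range(n_s):
        plan = plan_participation(population, model, rng_season)
        for event in range(n_t):
            entrants = select_entrants(event, plan, population,
                                       config.pool_size)
            if len(entrants) == 0:
                skipped.append((season, event))
                continue
            rng_event = np.random.default_rng(seed_seq.spawn(1)[0])
            participants = [population.fencer(int(i)) for i in entrants]
            result = run_tournament(participants, config, rng_event,
                                    event_index=event)
            update_rolling_ranking(population, event, result, rng_season,
                                   config.skipped_event_points)
            events.append(EventRecord(
                season=season,
                event_index=event,
                entrants=entrants.copy(),
                placements=np.array([result.placements[int(i)]
                                     for i in entrants], dtype=int),
                points=np.array([result.points[int(i)] for i in entrants],
                                dtype=float),
            ))
        season_end_ranks[season] = population.ranks
        season_end_points[season] = population.total_points

    return RunOutput(talents=population.talents,
                     season_end_ranks=season_end_ranks,
                     season_end_points=season_end_points,
                     events=events, skipped_events=skipped)


def run_simulation(config: SimulationConfig,
                   seed: Optional[int] = None,
                   n_runs: Optional[int] = None) -> SimulationOutput:
    """Run ``n_runs`` independent replicates (default from the config)."""
    if seed is None:
        seed = config.rng_seed
    if n_runs is None:
        n_runs = config.n_runs
    root = np.random.SeedSequence(seed)
    runs = [run_single(config, child) for child in root.spawn(n_runs)]
    return SimulationOutput(config=config, root_seed=seed, runs=runs)
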