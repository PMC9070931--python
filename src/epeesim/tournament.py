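"""One full competition: pools, classification, cut, and direct elimination.

Entrants, ordered by the current overall ranking, are renumbered 1..N for
the event; those positions drive the serpentine pool allocation and the
ranking-difference term of the double-hit fraction. After the round of
pools (round-robin groups of 6, classified by V/M, then HS-HR, then HS,
then lots) the top 70% qualify for a knockout table: with Q qualifiers and
S the largest power of two <= Q, the lowest 2(Q-S) seeds fence a
preliminary round while seeds 1..2S-Q advance directly; the table of S then
pairs seed s with seed S+1-s in the canonical bracket so the top two seeds
can only meet in the final. Losers of the round of 2^k are placed
2^(k-1)+1 .. 2^k ordered by their after-pool classification; both
semi-final losers share 3rd place.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bouts import BoutResult, _simulate_bout, double_hit_fraction, \
    draw_tournament_form
from .config import PointsScale, SimulationConfig

__all__ = [
    "PoolRecord",
    "Bracket",
    "TournamentResult",
    "allocate_pools",
    "run_pool_round",
    "classify_after_pools",
    "qualification_cut",
    "build_de_bracket",
    "bracket_order",
    "run_de",
    "assign_points",
    "run_tournament",
]


@dataclass
class PoolRecord:
    """Per-fencer pool tally: victories V over bouts M, hits scored/received."""

    fencer_id: int
    v: int = 0
    m: int = 0
    hs: int = 0
    hr: int = 0

    @property
    def indicator(self) -> float:
        """The V/M classification index."""
        return self.v / self.m if self.m else 0.0


@dataclass(frozen=True)
class Bracket:
    """Direct-elimination table built from the after-pool classification.

    ``seeds[s - 1]`` is the fencer id seeded ``s`` (1-based, after-pool
    order). ``size`` is the table size S; the ``n_preliminary`` bouts pair
    seed ``S - B + k`` with seed ``Q + 1 - k`` and their winners fill table
    slots ``S - B + 1 .. S`` while seeds ``1 .. S - B`` have a bye into the
    table.
    """

    seeds: tuple[int, ...]
    size: int
    preliminary_pairs: tuple[tuple[int, int], ...]   # (higher seed, lower seed)
    bye_seeds: tuple[int, ...]
    slot_order: tuple[int, ...]                      # table slots in bracket order

    @property
    def n_qualified(self) -> int:
        return len(self.seeds)

    @property
    def n_preliminary(self) -> int:
        return len(self.preliminary_pairs)


@dataclass
class TournamentResult:
    """Everything produced by one simulated competition."""

    event_index: int
    entrants: np.ndarray            # fencer ids in initial-position order
    initial_positions: dict[int, int]
    form: dict[int, float]
    pool_records: dict[int, PoolRecord]
    after_pool_classification: list[int]
    bracket: Bracket
    placements: dict[int, int]      # fencer id -> final placement
    points: dict[int, float]
    de_bouts: list[BoutResult] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return len(self.entrants)

    @property
    def winner(self) -> int:
        return next(f for f, p in self.placements.items() if p == 1)

    def classification_frame(self) -> pd.DataFrame:
        ids = list(self.placements)
        return pd.DataFrame(
            {
                "event": self.event_index,
                "fencer_id": ids,
                "initial_position": [self.initial_positions[f] for f in ids],
                "final_placement": [self.placements[f] for f in ids],
                "points": [self.points[f] for f in ids],
            }
        ).sort_values(["final_placement", "initial_position"], ignore_index=True)

    def pool_frame(self) -> pd.DataFrame:
        recs = self.pool_records.values()
        return pd.DataFrame(
            {
                "event": self.event_index,
                "fencer_id": [r.fencer_id for r in recs],
                "v": [r.v for r in recs],
                "m": [r.m for r in recs],
                "hs": [r.hs for r in recs],
                "hr": [r.hr for r in recs],
            }
        )


# --------------------------------------------------------------------------- #
# Pools
# --------------------------------------------------------------------------- #


def allocate_pools(seeded_participants: Sequence[int],
                   pool_size: int = 6) -> list[list[int]]:
    """Serpentine allocation: walking the seeding list, pools are filled
    left-to-right on odd grid rows and right-to-left on even rows, so every
    pool receives one fencer from each seeding band."""
    n = len(seeded_participants)
    if n == 0 or n % pool_size != 0:
        raise ValueError(
            f"participant count {n} is not a positive multiple of {pool_size}"
        )
    n_pools = n // pool_size
    pools: list[list[int]] = [[] for _ in range(n_pools)]
    it = iter(seeded_participants)
    for row in range(pool_size):
        cols = range(n_pools) if row % 2 == 0 else range(n_pools - 1, -1, -1)
        for c in cols:
            pools[c].append(next(it))
    return pools


def run_pool_round(pools: Sequence[Sequence[int]],
                   talents: Mapping[int, float],
                   positions: Mapping[int, int],
                   n_participants: int,
                   config: SimulationConfig,
                   form: Mapping[int, float],
                   rng: np.random.Generator) -> dict[int, PoolRecord]:
    """Round-robin every pool: C(6,2) = 15 bouts each, tallying V/M/HS/HR."""
    records = {f: PoolRecord(f) for pool in pools for f in pool}
    for pool in pools:
        for f1, f2 in itertools.combinations(pool, 2):
            fd = double_hit_fraction(
                0.5 * (talents[f1] + talents[f2]),
                positions[f1], positions[f2], n_participants,
                config.double_prefactor,
            )
            res = _simulate_bout(f1, f2, talents[f1], talents[f2],
                                 form[f1], form[f2], fd, config, rng,
                                 config.pool_target_hits, 1,
                                 config.pool_duration)
            r1, r2 = records[f1], records[f2]
            r1.m += 1
            r2.m += 1
            r1.hs += res.score_1
            r1.hr += res.score_2
            r2.hs += res.score_2
            r2.hr += res.score_1
            records[res.winner].v += 1
    return records


def classify_after_pools(records: Mapping[int, PoolRecord],
                         rng: np.random.Generator) -> list[int]:
    """Single general classification: V/M, then HS - HR, then HS, then lots."""
    ids = list(records)
    lots = dict(zip(ids, rng.random(len(ids)).tolist()))

    def key(f: int) -> tuple[float, int, int, float]:
        r = records[f]
        return (-r.indicator, -(r.hs - r.hr), -r.hs, lots[f])

    return sorted(ids, key=key)


def qualification_cut(classification: Sequence[int],
                      qualified_fraction: float) -> list[int]:
    """Top round(fraction * N) fencers advance (round half-up, so 100 -> 70)."""
    if not classification:
        raise ValueError("classification must be non-empty")
    n_q = int(np.floor(qualified_fraction * len(classification) + 0.5))
    n_q = max(1, min(n_q, len(classification)))
    return list(classification[:n_q])


# --------------------------------------------------------------------------- #
# Direct elimination
# --------------------------------------------------------------------------- #


def bracket_order(size: int) -> tuple[int, ...]:
    """Canonical bracket order of seeds 1..size (a power of two): adjacent
    entries fence, seed s meets seed size+1-s in the first round, and the
    top two seeds can only meet in the final."""
    if size < 1 or size & (size - 1):
        raise ValueError(f"table size must be a power of two, got {size}")
    order = [1]
    while len(order) < size:
        m = 2 * len(order) + 1
        order = [x for s in order for x in (s, m - s)]
    return tuple(order)


def build_de_bracket(qualified: Sequence[int]) -> Bracket:
    """Bracket for Q qualifiers: table size S = largest power of two <= Q,
    B = Q - S preliminary bouts pairing seed S-B+k with seed Q+1-k."""
    q = len(qualified)
    if q < 2:
        raise ValueError(f"need at least 2 qualified fencers, got {q}")
    s = 1
    while s * 2 <= q:
        s *= 2
    b = q - s
    prelims = tuple((s - b + k, q + 1 - k) for k in range(1, b + 1))
    byes = tuple(range(1, s - b + 1))
    return Bracket(seeds=tuple(qualified), size=s, preliminary_pairs=prelims,
                   bye_seeds=byes, slot_order=bracket_order(s))


def run_de(bracket: Bracket,
           talents: Mapping[int, float],
           positions: Mapping[int, int],
           n_participants: int,
           config: SimulationConfig,
           form: Mapping[int, float],
           rng: np.random.Generator,
           bout_log: list[BoutResult] | None = None) -> dict[int, int]:
    """Play the knockout and return final placements for all qualifiers.

    Placements: winner 1, finalist 2, both semi-final losers 3; losers of
    the round of 2^k take 2^(k-1)+1 .. 2^k ordered by after-pool seed;
    preliminary-round losers follow the whole table field, again in seed
    order.
    """
    seeds = bracket.seeds
    q = len(seeds)
    s = bracket.size
    seed_of = {seeds[i]: i + 1 for i in range(q)}

    def fight(fa: int, fb: int) -> BoutResult:
        fd = double_hit_fraction(
            0.5 * (talents[fa] + talents[fb]),
            positions[fa], positions[fb], n_participants,
            config.double_prefactor,
        )
        res = _simulate_bout(fa, fb, talents[fa], talents[fb],
                             form[fa], form[fb], fd, config, rng,
                             config.de_target_hits, config.de_n_periods,
                             config.de_period_duration)
        if bout_log is not None:
            bout_log.append(res)
        return res

    placements: dict[int, int] = {}

    # Preliminary round fills table slots S-B+1 .. S; its losers are placed
    # just below the full table field.
    occupant = {slot: seeds[slot - 1] for slot in bracket.bye_seeds}
    prelim_losers: list[int] = []
    for hi, lo in bracket.preliminary_pairs:
        res = fight(seeds[hi - 1], seeds[lo - 1])
        occupant[hi] = res.winner
        prelim_losers.append(seeds[hi - 1] if res.winner != seeds[hi - 1]
                             else seeds[lo - 1])
    for offset, f in enumerate(sorted(prelim_losers, key=seed_of.__getitem__)):
        placements[f] = s + 1 + offset

    # Main table.
    field_ids = [occupant[slot] for slot in bracket.slot_order]
    size = s
    while size > 1:
        winners: list[int] = []
        losers: list[int] = []
        for i in range(0, size, 2):
            res = fight(field_ids[i], field_ids[i + 1])
            winners.append(res.winner)
            losers.append(field_ids[i + 1] if res.winner == field_ids[i]
                          else field_ids[i])
        if size == 2:
            placements[losers[0]] = 2
        elif size == 4:
            for f in losers:
                placements[f] = 3          # ex aequo third
        else:
            for offset, f in enumerate(sorted(losers, key=seed_of.__getitem__)):
                placements[f] = size // 2 + 1 + offset
        field_ids = winners
        size //= 2
    placements[field_ids[0]] = 1
    return placements


def assign_points(final_classification: Mapping[int, int],
                  points_scale: PointsScale) -> dict[int, float]:
    """Map every fencer's final placement through the points-scale bands."""
    return {f: points_scale.points_for(p) for f, p in final_classification.items()}


# --------------------------------------------------------------------------- #
# Orchestration
# --------------------------------------------------------------------------- #


def run_tournament(participants, config: SimulationConfig,
                   rng: np.random.Generator, event_index: int = 0,
                   keep_de_bouts: bool = False) -> TournamentResult:
    """Run one full competition.

    ``participants`` must be ordered best-to-worst by the current overall
    ranking and carry ``id`` and ``talent`` attributes (e.g. ``Fencer``
    views); their order defines the event-internal initial positions 1..N.
    The participant count must be a multiple of the pool size.
    """
    parts = list(participants)
    n = len(parts)
    if n < config.pool_size:
        raise ValueError(f"need at least {config.pool_size} participants, got {n}")
    if n % config.pool_size != 0:
        raise ValueError(
            f"participant count {n} must be a multiple of pool size "
            f"{config.pool_size}"
        )
    ids = np.array([p.id for p in parts], dtype=int)
    talents = {p.id: float(p.talent) for p in parts}
    positions = {p.id: i + 1 for i, p in enumerate(parts)}

    form = draw_tournament_form(ids.tolist(), rng, config.mean_chance_low,
                                config.mean_chance_high)
    pools = allocate_pools(ids.tolist(), config.pool_size)
    records = run_pool_round(pools, talents, positions, n, config, form, rng)
    classification = classify_after_pools(records, rng)
    qualified = qualification_cut(classification, config.qualified_fraction)
    bracket = build_de_bracket(qualified)
    bout_log: list[BoutResult] | None = [] if keep_de_bouts else None
    placements = run_de(bracket, talents, positions, n, config, form, rng,
                        bout_log)

    # The non-qualified 30% fill the bottom placements in after-pool order.
    for offset, f in enumerate(classification[len(qualified):]):
        placements[f] = len(qualified) + 1 + offset

    points = assign_points(placements, config.points_scale)
    return TournamentResult(
        event_index=event_index,
        entrants=ids,
        initial_positions=positions,
        form=form,
        pool_records=records,
        after_pool_classification=classification,
        bracket=bracket,
        placements=placements,
        points=points,
        de_bouts=bout_log or [],
    )
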