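"""Touch-by-touch bout simulation.

Every touch opportunity compares the two fencers' touch quantities

    P_k = a * T_k + (1 - a) * L_k,    k = 1, 2

where ``a`` is the talent strength, ``T_k`` the fixed talent and ``L_k`` a
per-touch chance draw, uniform on [Lbar_k - w, Lbar_k + w] around the
fencer's tournament-level mean chance ("form") Lbar_k. Before the
comparison, a double-hit occurs with probability F_d:

    F_d = c * [ (1 - <T>) / 2 + (1 - |r1 - r2| / N) / 2 ],  c = 0.4

so doubles are more likely between weaker and closely-ranked opponents.
Pool bouts run to 5 hits in one 3-minute period; direct-elimination bouts to
15 hits over three 3-minute periods. A tie at the end of regulation goes to
a priority minute: a coin flip assigns priority, a single (non-double) touch
decides, and on timeout the priority holder wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from .config import SimulationConfig

__all__ = [
    "SINGLE_1",
    "SINGLE_2",
    "DOUBLE",
    "BoutResult",
    "PriorityOutcome",
    "draw_tournament_form",
    "double_hit_fraction",
    "simulate_touch_event",
    "simulate_pool_bout",
    "simulate_de_bout",
    "priority_minute",
]

# Touch-event outcomes. ``simulate_touch_event`` returns None for the
# measure-zero exact tie P_1 == P_2 (no touch awarded).
SINGLE_1 = 1
SINGLE_2 = 2
DOUBLE = 0


@dataclass(frozen=True)
class BoutResult:
    """Outcome of one bout, from fencer 1's perspective for the scores."""

    fencer_1: int
    fencer_2: int
    score_1: int
    score_2: int
    winner: int
    ended_by: str                 # "target-score" | "time-expiry" | "priority"
    priority_holder: Optional[int]
    decided_by_touch: bool        # meaningful only when ended_by == "priority"
    elapsed: float                # seconds of fencing time


@dataclass(frozen=True)
class PriorityOutcome:
    winner: int
    priority_holder: int
    decided_by_touch: bool
    score_1: int
    score_2: int
    elapsed: float


def draw_tournament_form(participants: Iterable[int], rng: np.random.Generator,
                         low: float = 0.3, high: float = 0.7) -> dict[int, float]:
    """Per-fencer mean chance Lbar, drawn once per tournament, uniform on
    [low, high]; it stays fixed for the whole competition ("form of the day")."""
    ids = list(participants)
    if not ids:
        raise ValueError("participant set must be non-empty")
    draws = rng.uniform(low, high, size=len(ids))
    return dict(zip(ids, draws.tolist()))


def double_hit_fraction(mean_talent: float, r1: int, r2: int,
                        n_participants: int, prefactor: float = 0.4) -> float:
    """Double-hit probability for a bout.

    ``mean_talent`` is the opponents' average talent; ``r1``/``r2`` their
    positions in the event's initial ranking (1..N). Both contributions have
    equal weight and the prefactor confines the result to [0, prefactor].
    """
    if not 0.0 < mean_talent <= 1.0:
        raise ValueError(f"mean talent must lie in (0, 1], got {mean_talent}")
    if r1 == r2:
        raise ValueError("opponents cannot share an initial ranking position")
    for r in (r1, r2):
        if not 1 <= r <= n_participants:
            raise ValueError(
                f"rank {r} outside 1..{n_participants}"
            )
    rdiff = abs(r1 - r2) / n_participants
    return prefactor * (0.5 * (1.0 - mean_talent) + 0.5 * (1.0 - rdiff))


def simulate_touch_event(a: float, t1: float, t2: float,
                         lbar1: float, lbar2: float, fd: float,
                         halfwidth: float, rng: np.random.Generator
                         ) -> Optional[int]:
    """One touch opportunity: DOUBLE, SINGLE_1, SINGLE_2, or None on the
    exact tie P_1 == P_2 (possible only for degenerate draws, e.g. a == 1
    with equal talents)."""
    if fd > rng.random():
        return DOUBLE
    b = 1.0 - a
    l1 = lbar1 + halfwidth * (2.0 * rng.random() - 1.0)
    l2 = lbar2 + halfwidth * (2.0 * rng.random() - 1.0)
    p1 = a * t1 + b * l1
    p2 = a * t2 + b * l2
    if p1 > p2:
        return SINGLE_1
    if p2 > p1:
        return SINGLE_2
    return None


def _priority(id1: int, id2: int, t1: float, t2: float,
              lb1: float, lb2: float, fd: float,
              config: SimulationConfig, rng: np.random.Generator,
              s1: int, s2: int) -> PriorityOutcome:
    """Priority minute on tied scores: first non-double touch decides;
    doubles never update the score; timeout favours the priority holder."""
    holder = id1 if rng.random() < 0.5 else id2
    a = config.talent_strength
    w = config.chance_halfwidth
    tmin, tmax = config.touch_interval_min, config.touch_interval_max
    span = tmax - tmin
    t = 0.0
    while True:
        dt = tmin + span * rng.random()
        if t + dt > config.priority_duration:
            break
        t += dt
        out = simulate_touch_event(a, t1, t2, lb1, lb2, fd, w, rng)
        if out == SINGLE_1:
            return PriorityOutcome(id1, holder, True, s1 + 1, s2, t)
        if out == SINGLE_2:
            return PriorityOutcome(id2, holder, True, s1, s2 + 1, t)
        # DOUBLE or exact tie: no score update, clock keeps running
    return PriorityOutcome(holder, holder, False, s1, s2,
                           config.priority_duration)


def _simulate_bout(id1: int, id2: int, t1: float, t2: float,
                   lb1: float, lb2: float, fd: float,
                   config: SimulationConfig, rng: np.random.Generator,
                   target: int, n_periods: int, period_len: float
                   ) -> BoutResult:
    """Regulation periods plus, if tied, the priority minute.

    The inter-touch interval in progress when a period expires is discarded
    and redrawn at the start of the next period.
    """
    a = config.talent_strength
    w = config.chance_halfwidth
    tmin, tmax = config.touch_interval_min, config.touch_interval_max
    span = tmax - tmin
    annul = config.double_at_match_point == "annul"
    s1 = s2 = 0
    for p in range(n_periods):
        t = 0.0
        while True:
            dt = tmin + span * rng.random()
            if t + dt > period_len:
                break
            t += dt
            out = simulate_touch_event(a, t1, t2, lb1, lb2, fd, w, rng)
            if out == DOUBLE:
                if annul and s1 == target - 1 and s2 == target - 1:
                    continue
                s1 += 1
                s2 += 1
            elif out == SINGLE_1:
                s1 += 1
            elif out == SINGLE_2:
                s2 += 1
            else:
                continue
            if s1 >= target or s2 >= target:
                elapsed = p * period_len + t
                if s1 != s2:
                    winner = id1 if s1 > s2 else id2
                    return BoutResult(id1, id2, s1, s2, winner, "target-score",
                                      None, False, elapsed)
                # simultaneous match point reached by a double: tied, priority
                pr = _priority(id1, id2, t1, t2, lb1, lb2, fd, config, rng,
                               s1, s2)
                return BoutResult(id1, id2, pr.score_1, pr.score_2, pr.winner,
                                  "priority", pr.priority_holder,
                                  pr.decided_by_touch, elapsed + pr.elapsed)
    regulation = n_periods * period_len
    if s1 != s2:
        winner = id1 if s1 > s2 else id2
        return BoutResult(id1, id2, s1, s2, winner, "time-expiry", None,
                          False, regulation)
    pr = _priority(id1, id2, t1, t2, lb1, lb2, fd, config, rng, s1, s2)
    return BoutResult(id1, id2, pr.score_1, pr.score_2, pr.winner, "priority",
                      pr.priority_holder, pr.decided_by_touch,
                      regulation + pr.elapsed)


def _form_of(form: Mapping[int, float], fid: int) -> float:
    try:
        return form[fid]
    except KeyError:
        raise KeyError(f"fencer {fid} has no tournament form drawn") from None


def simulate_pool_bout(fencer_1, fencer_2, config: SimulationConfig,
                       form: Mapping[int, float], fd: float,
                       rng: np.random.Generator) -> BoutResult:
    """Pool bout: first to ``pool_target_hits`` (5) within one period."""
    return _simulate_bout(fencer_1.id, fencer_2.id, fencer_1.talent,
                          fencer_2.talent, _form_of(form, fencer_1.id),
                          _form_of(form, fencer_2.id), fd, config, rng,
                          config.pool_target_hits, 1, config.pool_duration)


def simulate_de_bout(fencer_1, fencer_2, config: SimulationConfig,
                     form: Mapping[int, float], fd: float,
                     rng: np.random.Generator) -> BoutResult:
    """Direct-elimination bout: first to ``de_target_hits`` (15) over
    ``de_n_periods`` periods of ``de_period_duration`` seconds."""
    return _simulate_bout(fencer_1.id, fencer_2.id, fencer_1.talent,
                          fencer_2.talent, _form_of(form, fencer_1.id),
                          _form_of(form, fencer_2.id), fd, config, rng,
                          config.de_target_hits, config.de_n_periods,
                          config.de_period_duration)


def priority_minute(fencer_1, fencer_2, config: SimulationConfig,
                    form: Mapping[int, float], fd: float,
                    rng: np.random.Generator,
                    score_1: int = 0, score_2: int = 0) -> PriorityOutcome:
    """Stand-alone priority minute (scores must be tied on entry)."""
    if score_1 != score_2:
        raise ValueError("priority is only fenced on tied scores")
    return _priority(fencer_1.id, fencer_2.id, fencer_1.talent,
                     fencer_2.talent, _form_of(form, fencer_1.id),
                     _form_of(form, fencer_2.id), fd, config, rng,
                     score_1, score_2)
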