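"""Within-cage dominance ranking from trial records.

Scoring follows the standard cage-hierarchy protocol: within a session
every pair of cage-mates runs a 5-trial block; the rat winning the
majority of trials is the block's clear winner; each trial win is worth
two points and a loss zero.  Summing points over a rat's three pairings
gives its session score (0-30), and scores order the four cage-mates
into ranks 1-4.

Equal scores between two rats are broken by the head-to-head outcome of
their own block in that session, the winner ranked higher.  For ties the
head-to-head rule cannot settle (three- or four-way ties with a cyclic
beat pattern), a deterministic fallback applies: total trial wins in the
session, then canonical rat id.  Every fallback use is recorded in
``SessionRanking.tiebreaks_applied`` so downstream consumers can see
where policy, not data, decided an ordering.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .contest_io import Phase, TrialRecord

__all__ = [
    "PairSessionOutcome",
    "SessionRanking",
    "RankTrajectory",
    "score_pair_session",
    "tally_points",
    "rank_session",
    "build_trajectories",
    "rank_study",
    "ranking_table",
]


@dataclass(frozen=True)
class PairSessionOutcome:
    """Result of one pair's trial block in one session."""

    session: int
    pair: tuple[str, str]
    wins: Mapping[str, int]
    session_winner: str
    phase: Phase = Phase.I

    @property
    def n_trials(self) -> int:
        return sum(self.wins.values())

    @property
    def session_loser(self) -> str:
        a, b = self.pair
        return b if self.session_winner == a else a


@dataclass(frozen=True)
class SessionRanking:
    """Points and ranks of the four cage-mates for one session."""

    cage_id: str
    session: int
    points: Mapping[str, int]
    ranks: Mapping[str, int]
    tiebreaks_applied: tuple[tuple[frozenset, str], ...] = ()


@dataclass(frozen=True)
class RankTrajectory:
    """A rat's within-cage rank across sessions; ``None`` marks a gap."""

    rat_id: str
    ranks: tuple[int | None, ...]

    @property
    def complete(self) -> bool:
        return all(r is not None for r in self.ranks)


def score_pair_session(trials: Sequence[TrialRecord]) -> PairSessionOutcome:
    """Reduce one pair's trial block to win counts and a session winner.

    All trials must share pair, session and phase; the trial count must
    be odd so a strict majority winner always exists.
    """
    if not trials:
        raise ValueError("empty trial block")
    first = trials[0]
    if any(
        t.pair != first.pair or t.session != first.session or t.phase is not first.phase
        for t in trials
    ):
        raise ValueError("trials mix pairs, sessions or phases")
    if len(trials) % 2 == 0:
        raise ValueError(
            f"even trial count ({len(trials)}): majority winner is ambiguous"
        )
    a, b = first.pair
    wins = {a: sum(t.winner == a for t in trials), b: sum(t.winner == b for t in trials)}
    winner = a if wins[a] > wins[b] else b
    return PairSessionOutcome(
        session=first.session,
        pair=first.pair,
        wins=wins,
        session_winner=winner,
        phase=first.phase,
    )


def tally_points(outcomes: Sequence[PairSessionOutcome]) -> dict[str, int]:
    """Sum points over a full cage-session (two points per trial won).

    Requires the complete round robin: all six unordered pairs of the
    four rats appearing in ``outcomes``.  Conservation holds by
    construction: total points = 2 x total trials (60 at the default
    five trials per pair).
    """
    rats = sorted({r for o in outcomes for r in o.pair})
    if len(rats) != 4:
        raise ValueError(f"expected 4 rats in a cage-session, found {len(rats)}")
    expected = set(itertools.combinations(rats, 2))
    present = {o.pair for o in outcomes}
    if present != expected:
        missing = sorted(expected - present)
        raise ValueError(f"incomplete round robin; missing pair(s) {missing}")
    points = {r: 0 for r in rats}
    for o in outcomes:
        for rat, w in o.wins.items():
            points[rat] += 2 * w
    return points


def _head_to_head_order(
    tied: Sequence[str], by_pair: Mapping[tuple[str, str], PairSessionOutcome]
) -> list[str] | None:
    """Order a tied set by session wins against the other tied rats.

    Returns None unless the within-set win counts are all distinct,
    i.e. the head-to-head record yields a strict order (for two rats
    this is exactly the pairwise rule: the block winner ranks higher).
    """
    wins_in_set = {r: 0 for r in tied}
    for x, y in itertools.combinations(sorted(tied), 2):
        outcome = by_pair.get((x, y))
        if outcome is None:
            return None
        wins_in_set[outcome.session_winner] += 1
    if len(set(wins_in_set.values())) != len(tied):
        return None
    return sorted(tied, key=lambda r: -wins_in_set[r])


def rank_session(
    points: Mapping[str, int],
    outcomes: Sequence[PairSessionOutcome],
    cage_id: str = "",
) -> SessionRanking:
    """Order a cage-session by points, breaking ties deterministically.

    Tie policy, in order: (1) head-to-head within the tied set where it
    yields a strict order (the standard pairwise rule when two rats
    tie); (2) total trial wins in the session; (3) canonical rat id.
    Applied rules are logged per tied set.
    """
    by_pair = {o.pair: o for o in outcomes}
    trial_wins: dict[str, int] = defaultdict(int)
    for o in outcomes:
        for rat, w in o.wins.items():
            trial_wins[rat] += w

    order: list[str] = []
    tiebreaks: list[tuple[frozenset, str]] = []
    for pts in sorted(set(points.values()), reverse=True):
        tied = sorted(r for r in points if points[r] == pts)
        if len(tied) == 1:
            order += tied
            continue
        h2h = _head_to_head_order(tied, by_pair)
        if h2h is not None:
            order += h2h
            tiebreaks.append((frozenset(tied), "head_to_head"))
            continue
        if len({trial_wins[r] for r in tied}) == len(tied):
            order += sorted(tied, key=lambda r: -trial_wins[r])
            tiebreaks.append((frozenset(tied), "session_trial_wins"))
        else:
            order += sorted(tied, key=lambda r: (-trial_wins[r], r))
            tiebreaks.append((frozenset(tied), "canonical_id"))
    ranks = {rat: i + 1 for i, rat in enumerate(order)}
    session = outcomes[0].session if outcomes else 0
    return SessionRanking(
        cage_id=cage_id,
        session=session,
        points=dict(points),
        ranks=ranks,
        tiebreaks_applied=tuple(tiebreaks),
    )


def build_trajectories(
    rankings: Iterable[SessionRanking],
    sessions: Sequence[int] | None = None,
) -> dict[str, RankTrajectory]:
    """Assemble per-rat rank trajectories from session rankings.

    ``sessions`` defaults to the sorted session numbers present.  A rat
    absent from a session's ranking gets an explicit ``None`` gap —
    never an interpolated rank.
    """
    rankings = list(rankings)
    if sessions is None:
        sessions = sorted({r.session for r in rankings})
    by_session: dict[int, Mapping[str, int]] = {}
    for r in rankings:
        if r.session in by_session:
            raise ValueError(f"duplicate ranking for session {r.session}")
        by_session[r.session] = r.ranks
    rats = sorted({rat for r in rankings for rat in r.ranks})
    return {
        rat: RankTrajectory(
            rat_id=rat,
            ranks=tuple(by_session.get(s, {}).get(rat) for s in sessions),
        )
        for rat in rats
    }


def rank_study(
    records: Sequence[TrialRecord],
) -> tuple[dict[str, list[SessionRanking]], dict[str, RankTrajectory]]:
    """Run the full phase-I ranking pipeline over a record set.

    Groups phase-I trials by cage, session and pair; scores each block;
    tallies and ranks each cage-session.  Returns per-cage session
    rankings and per-rat trajectories.
    """
    blocks: dict[tuple[str, int, tuple[str, str]], list[TrialRecord]] = defaultdict(list)
    for rec in records:
        if rec.phase is Phase.I:
            blocks[(rec.cage_a, rec.session, rec.pair)].append(rec)

    by_cage_session: dict[tuple[str, int], list[PairSessionOutcome]] = defaultdict(list)
    for (cage, session, _pair), trials in sorted(blocks.items()):
        by_cage_session[(cage, session)].append(score_pair_session(trials))

    rankings: dict[str, list[SessionRanking]] = defaultdict(list)
    for (cage, _session), outcomes in sorted(by_cage_session.items()):
        points = tally_points(outcomes)
        rankings[cage].append(rank_session(points, outcomes, cage_id=cage))

    trajectories: dict[str, RankTrajectory] = {}
    for cage, cage_rankings in rankings.items():
        trajectories.update(build_trajectories(cage_rankings))
    return dict(rankings), trajectories


def ranking_table(rankings: Mapping[str, Sequence[SessionRanking]]) -> pd.DataFrame:
    """Flatten session rankings into a tidy table (one row per rat-session)."""
    rows = []
    for cage, cage_rankings in sorted(rankings.items()):
        for sr in cage_rankings:
            flagged = {rat for tied, _rule in sr.tiebreaks_applied for rat in tied}
            for rat in sorted(sr.ranks):
                rows.append(
                    {
                        "cage_id": cage,
                        "session": sr.session,
                        "rat_id": rat,
                        "points": sr.points[rat],
                        "rank": sr.ranks[rat],
                        "tiebreak_flag": rat in flagged,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["cage_id", "session", "rat_id", "points", "rank", "tiebreak_flag"],
    )
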