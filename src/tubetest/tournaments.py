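"""Phase II: inter-cage tournaments and their cross-tabulations.

In a tournament two cages meet: every rat of one cage contests every
rat of the other (4 x 4 = 16 cross-cage pairs), five trials per pair,
repeated over (by default) three sessions.  A *contest* is one
pair-session, won by the majority winner of its trial block — the same
semantics as a phase-I session winner.

Two re-analyses of the same contests are provided:

* **by genotype** — wins tallied for WT vs KO over cross-genotype
  contests, optionally filtered to a cage-type pairing (single-line vs
  single-line, mixed vs mixed, WT-cage vs mixed, KO-cage vs mixed);
* **by prior rank** — each rat carries a rank class from its phase-I
  home-cage hierarchy (ranks 1-2 = high, 3-4 = low).  The main contrast
  uses only high-vs-low contests (with two high and two low rats per
  cage these are 8 of the 16 pairs); conditional contrasts restrict to
  high-vs-high and low-vs-low contests and split those by genotype.

Each cross-tab carries a chi-square contrast against an even split.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .contest_io import CageType, Genotype, Phase, Roster, TrialRecord
from .ranking import RankTrajectory, score_pair_session
from .stats import WinContrast, chi2_even_split

__all__ = [
    "RankClass",
    "TournamentSpec",
    "ContestRecordII",
    "CrossTab",
    "RankClassTabs",
    "enumerate_pairs",
    "assign_rank_class",
    "phase2_contests",
    "genotype_crosstab",
    "rank_class_crosstab",
    "GENOTYPE_FILTERS",
]


class RankClass(str, enum.Enum):
    high = "high"
    low = "low"


@dataclass(frozen=True)
class TournamentSpec:
    """One inter-cage tournament: all 16 cross pairs, repeated sessions."""

    cage_a: str
    cage_b: str
    n_sessions: int = 3
    trials_per_pair: int = 5

    def __post_init__(self) -> None:
        if self.cage_a == self.cage_b:
            raise ValueError(f"a cage cannot meet itself ({self.cage_a})")


@dataclass(frozen=True)
class ContestRecordII:
    """One phase-II contest (pair-session), fully annotated."""

    pair: tuple[str, str]
    cage_pair: tuple[str, str]
    session: int
    session_winner: str
    wins: Mapping[str, int]
    genotypes: Mapping[str, Genotype]
    rank_classes: Mapping[str, RankClass]

    @property
    def is_cross_genotype(self) -> bool:
        a, b = self.pair
        return self.genotypes[a] is not self.genotypes[b]

    @property
    def class_pair(self) -> frozenset:
        return frozenset(self.rank_classes[r] for r in self.pair)


@dataclass(frozen=True)
class CrossTab:
    """Win counts by category over a set of contests, with attached test."""

    grouping: str
    wins: Mapping[str, int]
    n_contests: int
    chi2: WinContrast | None


@dataclass(frozen=True)
class RankClassTabs:
    """The prior-rank re-analysis: main high-vs-low tab plus conditionals."""

    high_vs_low: CrossTab
    high_conditional: CrossTab
    low_conditional: CrossTab


def enumerate_pairs(
    members_a: Sequence[str], members_b: Sequence[str]
) -> list[tuple[str, str]]:
    """All cross-cage pairs (Cartesian product), canonically ordered.

    The first element of each pair comes from ``members_a``.  Two cages
    of four yield the standard 16 pairs.
    """
    if set(members_a) & set(members_b):
        shared = sorted(set(members_a) & set(members_b))
        raise ValueError(f"cages share member(s) {shared}")
    return [(a, b) for a in sorted(members_a) for b in sorted(members_b)]


def assign_rank_class(
    trajectories: Mapping[str, RankTrajectory], policy: str = "final"
) -> dict[str, RankClass]:
    """Collapse each rat's phase-I trajectory to a high/low rank class.

    Ranks 1-2 map to high, 3-4 to low.  The aggregation of a trajectory
    to a single rank is a policy choice:

    * ``"final"`` (default) — the last phase-I session's rank, i.e. the
      rank the animal held at the end of within-cage testing;
    * ``"modal"`` — the most frequent rank (ties to the better rank);
    * ``"mean"`` — the mean rank rounded to the nearest integer (half
      rounds to the better rank).
    """
    classes: dict[str, RankClass] = {}
    for rat, traj in trajectories.items():
        ranks = [r for r in traj.ranks if r is not None]
        if not ranks:
            raise ValueError(f"rat {rat} has no phase-I ranking data")
        if policy == "final":
            rank = ranks[-1]
        elif policy == "modal":
            freq = Counter(ranks)
            top = max(freq.values())
            rank = min(r for r, c in freq.items() if c == top)
        elif policy == "mean":
            mean = sum(ranks) / len(ranks)
            rank = int(mean) if mean - int(mean) <= 0.5 else int(mean) + 1
        else:
            raise ValueError(f"unknown rank-class policy {policy!r}")
        classes[rat] = RankClass.high if rank <= 2 else RankClass.low
    return classes


def phase2_contests(
    records: Sequence[TrialRecord],
    roster: Roster,
    rank_classes: Mapping[str, RankClass],
) -> list[ContestRecordII]:
    """Reduce phase-II trial records to annotated contests.

    Groups trials by (pair, session), takes the majority winner of each
    block, and annotates both rats with genotype and phase-I rank class.
    """
    blocks: dict[tuple[tuple[str, str], int], list[TrialRecord]] = defaultdict(list)
    for rec in records:
        if rec.phase is Phase.II:
            blocks[(rec.pair, rec.session)].append(rec)
    contests = []
    for (pair, session), trials in sorted(blocks.items()):
        outcome = score_pair_session(trials)
        first = trials[0]
        for rat in pair:
            if rat not in rank_classes:
                raise ValueError(f"rat {rat} has no phase-I rank class")
        contests.append(
            ContestRecordII(
                pair=pair,
                cage_pair=(first.cage_a, first.cage_b),
                session=session,
                session_winner=outcome.session_winner,
                wins=dict(outcome.wins),
                genotypes={rat: roster.genotype_of(rat) for rat in pair},
                rank_classes={rat: rank_classes[rat] for rat in pair},
            )
        )
    return contests


#: cage-type pairing selected by each genotype-crosstab filter
GENOTYPE_FILTERS: dict[str, frozenset | None] = {
    "all": None,
    "single_vs_single": frozenset({CageType.WT_only, CageType.KO_only}),
    "mixed_vs_mixed": frozenset({CageType.mixed}),
    "WTcage_vs_mixed": frozenset({CageType.WT_only, CageType.mixed}),
    "KOcage_vs_mixed": frozenset({CageType.KO_only, CageType.mixed}),
}


def _tally(
    contests: Sequence[ContestRecordII],
    category_of: Mapping[str, str] | None = None,
    count: str = "contests",
) -> Counter:
    """Count wins per category; category_of maps rat -> category label."""
    wins: Counter = Counter()
    for c in contests:
        if count == "contests":
            wins[category_of[c.session_winner]] += 1
        elif count == "trials":
            for rat, w in c.wins.items():
                wins[category_of[rat]] += w
        else:
            raise ValueError(f"count must be 'contests' or 'trials', got {count!r}")
    return wins


def genotype_crosstab(
    contests: Sequence[ContestRecordII],
    roster: Roster,
    cage_filter: str = "all",
    count: str = "contests",
) -> CrossTab:
    """Tally WT vs KO wins over cross-genotype contests.

    ``cage_filter`` restricts to tournaments between specific cage
    types (see :data:`GENOTYPE_FILTERS`); same-genotype contests are
    excluded by definition.  ``count`` switches between contest-level
    (default) and trial-level tallies.
    """
    if cage_filter not in GENOTYPE_FILTERS:
        raise ValueError(
            f"unknown filter {cage_filter!r}; choose from {sorted(GENOTYPE_FILTERS)}"
        )
    wanted = GENOTYPE_FILTERS[cage_filter]
    selected = []
    for c in contests:
        if not c.is_cross_genotype:
            continue
        types = frozenset(roster.cage_type_of(cg) for cg in c.cage_pair)
        if wanted is not None and types != wanted:
            continue
        selected.append(c)
    if not selected:
        raise ValueError(f"no cross-genotype contests match filter {cage_filter!r}")
    category_of_all = {
        rat: c.genotypes[rat].value for c in selected for rat in c.pair
    }
    wins = _tally(selected, category_of_all, count)
    wt, ko = wins.get("WT", 0), wins.get("KO", 0)
    return CrossTab(
        grouping=f"genotype[{cage_filter}]",
        wins={"WT": wt, "KO": ko},
        n_contests=len(selected),
        chi2=chi2_even_split(wt, ko, "WT", "KO"),
    )


def rank_class_crosstab(
    contests: Sequence[ContestRecordII], count: str = "contests"
) -> RankClassTabs:
    """Re-analyse contests by phase-I rank class.

    The main tab keeps only high-vs-low contests (the informative half:
    high-vs-high and low-vs-low contests are excluded) and tallies wins
    by rank class.  The conditional tabs take the excluded contests —
    high-vs-high and low-vs-low separately — and, within each, tally
    cross-genotype wins WT vs KO.  An empty selection yields a tab with
    no attached test rather than an error, since e.g. a roster of
    all-high pairings legitimately empties the main tab.
    """
    high_low = [c for c in contests if c.class_pair == frozenset({RankClass.high, RankClass.low})]
    if high_low:
        cat = {rat: c.rank_classes[rat].value for c in high_low for rat in c.pair}
        wins = _tally(high_low, cat, count)
        hi, lo = wins.get("high", 0), wins.get("low", 0)
        main = CrossTab(
            grouping="rank_class[high_vs_low]",
            wins={"high": hi, "low": lo},
            n_contests=len(high_low),
            chi2=chi2_even_split(hi, lo, "high", "low"),
        )
    else:
        main = CrossTab("rank_class[high_vs_low]", {"high": 0, "low": 0}, 0, None)

    def conditional(klass: RankClass) -> CrossTab:
        name = f"genotype[{klass.value}_vs_{klass.value}]"
        same = [
            c
            for c in contests
            if c.class_pair == frozenset({klass}) and c.is_cross_genotype
        ]
        if not same:
            return CrossTab(name, {"WT": 0, "KO": 0}, 0, None)
        cat = {rat: c.genotypes[rat].value for c in same for rat in c.pair}
        wins = _tally(same, cat, count)
        wt, ko = wins.get("WT", 0), wins.get("KO", 0)
        return CrossTab(name, {"WT": wt, "KO": ko}, len(same),
                        chi2_even_split(wt, ko, "WT", "KO"))

    return RankClassTabs(
        high_vs_low=main,
        high_conditional=conditional(RankClass.high),
        low_conditional=conditional(RankClass.low),
    )
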