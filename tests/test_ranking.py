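"""Session scoring, point tallies, tie-breaking and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from tubetest.ranking import (
    PairSessionOutcome,
    build_trajectories,
    rank_session,
    rank_study,
    score_pair_session,
    tally_points,
)

from conftest import make_block
from oracle import oracle_rank

PAIRS = [("r1", "r2"), ("r1", "r3"), ("r1", "r4"),
         ("r2", "r3"), ("r2", "r4"), ("r3", "r4")]


def cage_session(wins_by_pair: dict[tuple[str, str], int], session: int = 1):
    """Outcomes for a full cage-session from per-pair win counts."""
    return [
        score_pair_session(make_block(a, b, wins_by_pair[(a, b)], session=session))
        for a, b in PAIRS
    ]


class TestScorePairSession:
    @pytest.mark.parametrize(
        "wins_a, expected_winner", [(3, "a"), (5, "a"), (2, "b"), (0, "b")]
    )
    def test_majority_winner(self, wins_a, expected_winner):
        outcome = score_pair_session(make_block("a", "b", wins_a))
        assert outcome.session_winner == expected_winner
        assert outcome.wins == {"a": wins_a, "b": 5 - wins_a}
        assert outcome.n_trials == 5

    def test_even_trial_count_is_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous|even"):
            score_pair_session(make_block("a", "b", 2, n_trials=4))

    def test_mixed_sessions_rejected(self):
        trials = make_block("a", "b", 3)[:3] + make_block("a", "b", 3, session=2)[:2]
        with pytest.raises(ValueError, match="mix"):
            score_pair_session(trials)


class TestTallyPoints:
    def test_sweep_gives_30_points_and_conservation(self):
        outcomes = cage_session(
            {p: (5 if p[0] == "r1" else 3) for p in PAIRS}
        )
        points = tally_points(outcomes)
        assert points["r1"] == 30                 # 3 opponents x 5 trials x 2
        assert sum(points.values()) == 60         # 30 trials x 2 points

    def test_winless_rat_scores_zero(self):
        wins = {p: 5 for p in PAIRS}              # first-listed always sweeps
        points = tally_points(cage_session(wins))
        assert points["r4"] == 0

    def test_missing_pair_is_incompleteness_error(self):
        outcomes = cage_session({p: 3 for p in PAIRS})[:5]
        with pytest.raises(ValueError, match="missing pair"):
            tally_points(outcomes)


class TestRankSession:
    def test_strict_ordering(self):
        outcomes = cage_session({p: 5 for p in PAIRS})
        ranking = rank_session(tally_points(outcomes), outcomes)
        assert ranking.ranks == {"r1": 1, "r2": 2, "r3": 3, "r4": 4}
        assert ranking.tiebreaks_applied == ()

    def test_two_way_tie_broken_by_head_to_head(self):
        # r1 and r2 tie on points; r2 beat r1 in their own block
        wins = {("r1", "r2"): 2, ("r1", "r3"): 5, ("r1", "r4"): 5,
                ("r2", "r3"): 4, ("r2", "r4"): 5, ("r3", "r4"): 3}
        outcomes = cage_session(wins)
        points = tally_points(outcomes)
        assert points["r1"] == points["r2"]
        ranking = rank_session(points, outcomes)
        assert ranking.ranks["r2"] < ranking.ranks["r1"]
        assert any(rule == "head_to_head" for _, rule in ranking.tiebreaks_applied)

    def test_cyclic_three_way_tie_uses_fallback_and_matches_oracle(self):
        # r1 > r2 > r3 > r1 head-to-head with equal points among the three
        wins = {("r1", "r2"): 4, ("r2", "r3"): 4, ("r1", "r3"): 1,
                ("r1", "r4"): 5, ("r2", "r4"): 5, ("r3", "r4"): 5}
        outcomes = cage_session(wins)
        points = tally_points(outcomes)
        assert len({points[r] for r in ("r1", "r2", "r3")}) == 1
        ranking = rank_session(points, outcomes)
        assert ranking.ranks == oracle_rank(points, outcomes)
        assert ranking.tiebreaks_applied  # fallback was logged

    def test_oracle_equivalence_on_random_cage_sessions(self):
        rng = np.random.default_rng(2024)
        for _ in range(500):
            wins = {p: int(rng.integers(0, 6)) for p in PAIRS}
            outcomes = cage_session(wins)
            points = tally_points(outcomes)
            ranking = rank_session(points, outcomes)
            assert ranking.ranks == oracle_rank(points, outcomes)
            assert sorted(ranking.ranks.values()) == [1, 2, 3, 4]

    def test_antisymmetry_under_relabelling(self):
        """Swapping every trial's winner inverts every pairwise outcome."""
        rng = np.random.default_rng(5)
        wins = {p: int(rng.integers(0, 6)) for p in PAIRS}
        flipped = {p: 5 - w for p, w in wins.items()}
        for (a, b) in PAIRS:
            o = score_pair_session(make_block(a, b, wins[(a, b)]))
            f = score_pair_session(make_block(a, b, flipped[(a, b)]))
            assert o.session_winner != f.session_winner


class TestTrajectories:
    def test_constant_and_alternating_trajectories(self):
        rankings = []
        for s in range(1, 11):
            swap = s % 2 == 0
            ranks = {"r1": 2 if swap else 1, "r2": 1 if swap else 2,
                     "r3": 3, "r4": 4}
            rankings.append(
                rank_session(
                    {r: (4 - rk) * 10 for r, rk in ranks.items()},
                    cage_session({p: 3 for p in PAIRS}, session=s),
                )
            )
        # constant rank-3 rat
        outcomes_all = build_trajectories(rankings)
        assert outcomes_all["r3"].ranks == (3,) * 10

    def test_missing_session_leaves_gap(self):
        outcomes1 = cage_session({p: 5 for p in PAIRS}, session=1)
        outcomes3 = cage_session({p: 5 for p in PAIRS}, session=3)
        rankings = [
            rank_session(tally_points(outcomes1), outcomes1),
            rank_session(tally_points(outcomes3), outcomes3),
        ]
        trajs = build_trajectories(rankings, sessions=[1, 2, 3])
        assert trajs["r1"].ranks == (1, None, 1)
        assert not trajs["r1"].complete

    def test_zero_volatility_simulation_gives_constant_trajectories(self):
        import tubetest as tt
        from tubetest.contest_io import CageType, StudyDesign

        scenario = tt.SimScenario(
            seed=3,
            design=StudyDesign(n_cages_by_type={CageType.WT_only: 2,
                                                CageType.KO_only: 0,
                                                CageType.mixed: 0}),
            sigma_theta=3.0, beta=50.0, delta_win=0.0, delta_loss=0.0,
            volatility_wt=0.0, volatility_ko=0.0,
            volatility_spread_wt=0.0, volatility_spread_ko=0.0, p_lock_ko=0.0,
        )
        sim = tt.simulate_phase1(scenario)
        _, trajectories = rank_study(sim.records)
        for traj in trajectories.values():
            assert len(set(traj.ranks)) == 1
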