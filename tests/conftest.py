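"""Shared fixtures: small simulated studies and record builders."""

from __future__ import annotations

import pytest

import tubetest as tt
from tubetest.contest_io import CageType, Phase, StudyDesign, TrialRecord


def make_block(
    rat_a: str,
    rat_b: str,
    wins_a: int,
    session: int = 1,
    cage: str = "C1",
    n_trials: int = 5,
    phase: Phase = Phase.I,
    cage_b: str | None = None,
) -> list[TrialRecord]:
    """A trial block where the first-named rat wins ``wins_a`` trials."""
    winners = [rat_a] * wins_a + [rat_b] * (n_trials - wins_a)
    return [
        TrialRecord(
            phase=phase,
            session=session,
            cage_a=cage,
            rat_a=rat_a,
            cage_b=cage_b or cage,
            rat_b=rat_b,
            trial_index=i + 1,
            winner=w,
        )
        for i, w in enumerate(winners)
    ]


@pytest.fixture(scope="session")
def default_sim():
    """One full two-phase study at the documented default scenario."""
    return tt.simulate_study(tt.default_paper_scenario(seed=11))


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(
        n_cages_by_type={CageType.WT_only: 1, CageType.KO_only: 1, CageType.mixed: 1}
    )


@pytest.fixture(scope="session")
def small_sim(small_design):
    """A three-cage study for cheap unit tests."""
    scenario = tt.SimScenario(seed=7, design=small_design)
    return tt.simulate_phase1(scenario)
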