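"""Latent-strength contest simulator with winner/loser dynamics.

No raw contest data accompany the study design this package analyses,
so the pipeline is exercised end-to-end on synthetic data generated
here.  The generator is a Bradley-Terry-style latent-strength model
with experience updating:

* each rat i carries a latent dominance strength ``theta_i``, drawn at
  study start from a genotype-specific baseline plus a between-animal
  spread (``theta0_wt``/``theta0_ko``, ``sigma_theta``);
* a trial between i and j is won by i with logistic probability
  ``1 / (1 + exp(-beta (theta_i - theta_j)))`` — ``beta`` is the
  discriminability of strength differences;
* after each pair-session, the majority (session) winner gains
  ``delta_win`` strength and the loser drops ``delta_loss`` — the
  winner/loser effect, the session being the behavioural unit; these
  increments are persistent (experience accumulates);
* on each session every rat's *effective* strength is its persistent
  strength plus a transient Gaussian perturbation ("form of the day")
  whose scale is genotype-specific (``volatility_wt``/``volatility_ko``)
  and further varies between animals (a median-one lognormal multiplier
  with genotype-specific log-scale ``volatility_spread_wt``/``_ko``).
  Day-to-day consistency is
  thus itself a persistent individual trait, which is what makes a
  rat's rank stability in the first half of testing predictive of its
  stability in the second half;
* with probability ``p_lock_ko`` a knockout rat adopts a fixed extreme
  strategy at study start — "bully" (pinned near ``+lock_magnitude``)
  or "submissive" (near ``-lock_magnitude``) with equal probability —
  and is thereafter immune to updating and volatility.  The pinned
  strength carries a persistent half-normal individual offset (scale
  ``lock_magnitude / 4``) beyond the extreme, so two same-strategy
  locked cage-mates are distinct animals rather than exact ties.
  Lock-in is what produces the characteristic bimodal split of
  knockout stability: a locked rat sits immovably at the top or bottom
  of its cage while unlocked knockouts churn.

Phase II reuses the strengths a rat has accumulated by the end of
phase I (experience carries over into contests with strangers), with
the same updating rules during tournament play.

All randomness flows through one seeded generator per simulation with a
documented draw order (weights, baseline strengths, lock assignments,
then per session: transient perturbations in sorted rat order, then
trials in canonical cage/pair order), so identical scenarios reproduce
byte-identical record sets.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .contest_io import (
    Cage,
    CageType,
    Genotype,
    Phase,
    Rat,
    Roster,
    StartSide,
    StudyDesign,
    TrialRecord,
)

__all__ = [
    "LockStrategy",
    "SimScenario",
    "SimResult",
    "win_probability",
    "build_default_roster",
    "default_tournament_roster",
    "simulate_phase1",
    "simulate_phase2",
    "simulate_study",
    "default_paper_scenario",
    "null_scenario",
]


class LockStrategy(str, enum.Enum):
    bully = "bully"
    submissive = "submissive"


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters of a synthetic two-phase study.

    Strengths are in arbitrary logit units — only their ratios to the
    volatility scales and (through ``beta``) to the trial noise matter.
    The defaults express the qualitative structure of the real study —
    wild-type dominance in mixed cages (a ~70% cross-genotype win
    fraction), higher knockout rank variance in single-line cages,
    wild-type stability as a persistent split-half trait, and a bimodal
    knockout stability distribution driven by lock-in; effect sizes are
    a modelling choice, not estimates (no raw data exist to fit them
    to).
    """

    seed: int = 0
    design: StudyDesign = field(default_factory=StudyDesign)
    theta0_wt: float = 2.9
    theta0_ko: float = -2.9
    sigma_theta: float = 1.9
    beta: float = 2.6
    delta_win: float = 0.05
    delta_loss: float = 0.05
    volatility_wt: float = 0.42
    volatility_ko: float = 6.5
    volatility_spread_wt: float = 0.5
    volatility_spread_ko: float = 0.2
    p_lock_ko: float = 0.30
    lock_magnitude: float = 5.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lock_ko <= 1.0):
            raise ValueError("p_lock_ko must be in [0, 1]")
        for name in ("sigma_theta", "beta", "delta_win", "delta_loss",
                     "volatility_wt", "volatility_ko",
                     "volatility_spread_wt", "volatility_spread_ko"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.lock_magnitude <= 0:
            raise ValueError("lock_magnitude must be positive")


@dataclass
class SimResult:
    """Simulated records plus the ground truth that generated them."""

    records: list[TrialRecord]
    theta_history: dict[str, list[float]]
    lock_assignments: dict[str, LockStrategy | None]
    roster: Roster
    final_theta: dict[str, float]
    rat_volatility: dict[str, float] = field(default_factory=dict)


def win_probability(theta_i: float, theta_j: float, beta: float) -> float:
    """Logistic per-trial win probability of rat i against rat j.

    Complementary by construction: p(i, j) + p(j, i) = 1; a zero
    discriminability makes every trial a fair coin.
    """
    x = beta * (theta_i - theta_j)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


# ---------------------------------------------------------------------------
# study population
# ---------------------------------------------------------------------------

_CAGE_PREFIX = {CageType.WT_only: "WT", CageType.KO_only: "KO", CageType.mixed: "MX"}


def build_default_roster(
    design: StudyDesign, rng: np.random.Generator | None = None
) -> Roster:
    """Construct the cage/rat population implied by a study design.

    Cages are named WT1.., KO1.., MX1..; rats <cage>a-<cage>d.  In a
    mixed cage rats a, b are wild-type and c, d knockout.  Cages are
    assigned to three cohorts round-robin.  If a generator is supplied,
    adult body weights are drawn (N(475, 55) g, clipped to the study's
    320-680 g range) — weight is deliberately independent of strength,
    matching the observed absence of a weight-rank relationship.
    """
    rats: dict[str, Rat] = {}
    cages: dict[str, Cage] = {}
    cage_index = 0
    for ctype in (CageType.WT_only, CageType.KO_only, CageType.mixed):
        for i in range(design.n_cages_by_type.get(ctype, 0)):
            cage_id = f"{_CAGE_PREFIX[ctype]}{i + 1}"
            cohort = cage_index % 3 + 1
            cage_index += 1
            members = []
            for k, letter in enumerate("abcd"):
                rat_id = f"{cage_id}{letter}"
                if ctype is CageType.WT_only:
                    genotype = Genotype.WT
                elif ctype is CageType.KO_only:
                    genotype = Genotype.KO
                else:
                    genotype = Genotype.WT if k < 2 else Genotype.KO
                weight = None
                if rng is not None:
                    weight = float(np.clip(rng.normal(475.0, 55.0), 320.0, 680.0))
                rats[rat_id] = Rat(rat_id, cage_id, genotype, cohort, weight)
                members.append(rat_id)
            cages[cage_id] = Cage(cage_id, ctype, tuple(members))
    return Roster(rats=rats, cages=cages)


def default_tournament_roster(roster: Roster) -> tuple[tuple[str, str, int], ...]:
    """The default phase-II pairings: one tournament per combination type.

    Four combination types are contested where the cages exist: a
    single-line WT cage vs a single-line KO cage; all pairings among the
    first three mixed cages; a WT cage vs a mixed cage; a KO cage vs a
    mixed cage.  The real study's full tournament roster per cohort is
    not documented, so this roster is an approximation that covers every
    cage-type pairing the analyses stratify on.
    """
    wt = sorted(c for c, cage in roster.cages.items() if cage.cage_type is CageType.WT_only)
    ko = sorted(c for c, cage in roster.cages.items() if cage.cage_type is CageType.KO_only)
    mx = sorted(c for c, cage in roster.cages.items() if cage.cage_type is CageType.mixed)
    pairings: list[tuple[str, str, int]] = []
    if wt and ko:
        pairings.append((wt[0], ko[0], 3))
    for a, b in itertools.combinations(mx[:3], 2):
        pairings.append((a, b, 3))
    if len(wt) > 1 and len(mx) > 3:
        pairings.append((wt[1], mx[3], 3))
    elif wt and mx:
        pairings.append((wt[0], mx[0], 3))
    if len(ko) > 1 and len(mx) > 4:
        pairings.append((ko[1], mx[4], 3))
    elif ko and mx:
        pairings.append((ko[0], mx[0], 3))
    return tuple(pairings)


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------


def _init_population(
    scenario: SimScenario, rng: np.random.Generator
) -> tuple[
    Roster,
    dict[str, float],
    dict[str, LockStrategy | None],
    dict[str, float],
]:
    roster = build_default_roster(scenario.design, rng)
    theta: dict[str, float] = {}
    for rat_id in sorted(roster.rats):
        base = (
            scenario.theta0_wt
            if roster.rats[rat_id].genotype is Genotype.WT
            else scenario.theta0_ko
        )
        theta[rat_id] = base + scenario.sigma_theta * float(rng.standard_normal())
    locks: dict[str, LockStrategy | None] = {r: None for r in roster.rats}
    locked = [
        rat_id
        for rat_id in sorted(roster.rats)
        if roster.rats[rat_id].genotype is Genotype.KO
        and float(rng.random()) < scenario.p_lock_ko
    ]
    # each locked rat is equally likely to get either strategy; the split
    # is balanced across the study (randomised to within one animal) so
    # strategy composition does not swamp the genotype effects
    order = list(rng.permutation(len(locked)))
    parity = int(rng.random() < 0.5)
    for pos, idx in enumerate(order):
        rat_id = locked[idx]
        strategy = (
            LockStrategy.bully
            if pos % 2 == parity
            else LockStrategy.submissive
        )
        locks[rat_id] = strategy
        # persistent individual offset beyond the extreme keeps
        # same-strategy cage-mates from being exact ties
        pinned = scenario.lock_magnitude + abs(
            float(rng.standard_normal())
        ) * scenario.lock_magnitude / 4.0
        theta[rat_id] = pinned if strategy is LockStrategy.bully else -pinned
    # per-animal day-to-day consistency trait: median-one lognormal
    # multiplier on the genotype volatility scale
    volatility: dict[str, float] = {}
    for rat_id in sorted(roster.rats):
        if roster.rats[rat_id].genotype is Genotype.WT:
            base_vol, spread = scenario.volatility_wt, scenario.volatility_spread_wt
        else:
            base_vol, spread = scenario.volatility_ko, scenario.volatility_spread_ko
        mult = 1.0
        if spread > 0:
            mult = math.exp(spread * float(rng.standard_normal()))
        volatility[rat_id] = base_vol * mult
    return roster, theta, locks, volatility


def _run_block(
    scenario: SimScenario,
    rng: np.random.Generator,
    theta: dict[str, float],
    effective: Mapping[str, float],
    locks: Mapping[str, LockStrategy | None],
    phase: Phase,
    session: int,
    cage_a: str,
    rat_a: str,
    cage_b: str,
    rat_b: str,
) -> list[TrialRecord]:
    """One 5-trial block; applies the winner/loser update afterwards.

    Win probabilities use the session's effective strengths; the
    winner/loser increments apply to the persistent strengths.
    """
    n = scenario.design.trials_per_pair
    p = win_probability(effective[rat_a], effective[rat_b], scenario.beta)
    u = rng.random(n)
    latencies = rng.lognormal(mean=math.log(8.0), sigma=0.5, size=n)
    records = []
    wins_a = 0
    for t in range(n):
        a_wins = bool(u[t] < p)
        wins_a += a_wins
        records.append(
            TrialRecord(
                phase=phase,
                session=session,
                cage_a=cage_a,
                rat_a=rat_a,
                cage_b=cage_b,
                rat_b=rat_b,
                trial_index=t + 1,
                winner=rat_a if a_wins else rat_b,
                latency_s=round(float(latencies[t]), 2),
                start_side=StartSide.left if t % 2 == 0 else StartSide.right,
            )
        )
    winner, loser = (rat_a, rat_b) if wins_a > n - wins_a else (rat_b, rat_a)
    if locks[winner] is None:
        theta[winner] += scenario.delta_win
    if locks[loser] is None:
        theta[loser] -= scenario.delta_loss
    return records


def _session_form(
    rng: np.random.Generator,
    theta: Mapping[str, float],
    locks: Mapping[str, LockStrategy | None],
    volatility: Mapping[str, float],
    rat_ids: Sequence[str],
) -> dict[str, float]:
    """Effective strengths for one session: persistent + transient form.

    Locked rats express their pinned strength exactly; everyone else
    gets a Gaussian perturbation at its own volatility scale, for this
    session only.
    """
    effective = dict(theta)
    for rat_id in sorted(rat_ids):
        if locks[rat_id] is not None:
            continue
        vol = volatility[rat_id]
        if vol > 0:
            effective[rat_id] = theta[rat_id] + vol * float(rng.standard_normal())
    return effective


def simulate_phase1(scenario: SimScenario) -> SimResult:
    """Simulate the within-cage hierarchy phase.

    Every cage runs all six pairs for a trial block per session across
    ``design.sessions_phase1`` sessions.  ``theta_history`` records each
    rat's strength entering every session, plus a final post-study
    snapshot (length ``sessions + 1``).
    """
    rng = np.random.default_rng(scenario.seed)
    roster, theta, locks, volatility = _init_population(scenario, rng)
    history: dict[str, list[float]] = {r: [] for r in roster.rats}
    records: list[TrialRecord] = []
    for session in range(1, scenario.design.sessions_phase1 + 1):
        for rat_id in roster.rats:
            history[rat_id].append(theta[rat_id])
        effective = _session_form(rng, theta, locks, volatility, list(roster.rats))
        for cage_id in sorted(roster.cages):
            members = sorted(roster.cages[cage_id].members)
            for rat_a, rat_b in itertools.combinations(members, 2):
                records += _run_block(
                    scenario, rng, theta, effective, locks, Phase.I, session,
                    cage_id, rat_a, cage_id, rat_b,
                )
    for rat_id in roster.rats:
        history[rat_id].append(theta[rat_id])
    return SimResult(
        records=records,
        theta_history=history,
        lock_assignments=locks,
        roster=roster,
        final_theta=dict(theta),
        rat_volatility=volatility,
    )


def simulate_phase2(
    scenario: SimScenario,
    phase1: SimResult,
    tournaments: Sequence[tuple[str, str, int]] | None = None,
    reset_theta: bool = False,
) -> SimResult:
    """Simulate inter-cage tournaments from the post-phase-I state.

    Strengths carry over from phase I and keep updating during play;
    each tournament session draws fresh transient form for the eight
    participating rats.  ``reset_theta=True`` ablates the experience
    carryover by redrawing every unlocked rat's strength from its
    genotype baseline — with carryover gone, a rat's phase-I rank no
    longer predicts tournament outcomes.

    Uses a fresh stream derived from the scenario seed so the phase is
    reproducible on its own as well as within :func:`simulate_study`.
    """
    rng = np.random.default_rng([scenario.seed, 2])
    roster = phase1.roster
    theta = dict(phase1.final_theta)
    locks = phase1.lock_assignments
    if tournaments is None:
        tournaments = scenario.design.tournaments or default_tournament_roster(roster)
    for cage_a, cage_b, _n in tournaments:
        for cage_id in (cage_a, cage_b):
            if cage_id not in roster.cages:
                raise ValueError(f"tournament references unknown cage {cage_id}")
    if reset_theta:
        for rat_id in sorted(roster.rats):
            if locks[rat_id] is None:
                base = (
                    scenario.theta0_wt
                    if roster.rats[rat_id].genotype is Genotype.WT
                    else scenario.theta0_ko
                )
                theta[rat_id] = base + scenario.sigma_theta * float(rng.standard_normal())
    records: list[TrialRecord] = []
    for cage_a, cage_b, n_sessions in tournaments:
        members_a = sorted(roster.cages[cage_a].members)
        members_b = sorted(roster.cages[cage_b].members)
        participants = members_a + members_b
        for session in range(1, n_sessions + 1):
            effective = _session_form(
                rng, theta, locks, phase1.rat_volatility, participants
            )
            for rat_a in members_a:
                for rat_b in members_b:
                    records += _run_block(
                        scenario, rng, theta, effective, locks, Phase.II, session,
                        cage_a, rat_a, cage_b, rat_b,
                    )
    return SimResult(
        records=records,
        theta_history=phase1.theta_history,
        lock_assignments=dict(locks),
        roster=roster,
        final_theta=dict(theta),
        rat_volatility=dict(phase1.rat_volatility),
    )


def simulate_study(
    scenario: SimScenario,
    tournaments: Sequence[tuple[str, str, int]] | None = None,
) -> SimResult:
    """Run both phases; records are concatenated (phase I then phase II)."""
    phase1 = simulate_phase1(scenario)
    phase2 = simulate_phase2(scenario, phase1, tournaments)
    return SimResult(
        records=phase1.records + phase2.records,
        theta_history=phase1.theta_history,
        lock_assignments=phase1.lock_assignments,
        roster=phase1.roster,
        final_theta=phase2.final_theta,
        rat_volatility=phase1.rat_volatility,
    )


def default_paper_scenario(seed: int = 0) -> SimScenario:
    """The documented default parameterization.

    Reproduces, qualitatively, the four phase-I phenotypes the analysis
    pipeline is built to detect: wild-type dominance in mixed cages;
    higher knockout rank variance in single-line cages; significant
    wild-type split-half stability correlation; and a bimodal knockout
    stability distribution (via lock-in).  The design is the standard
    3 WT + 4 KO + 7 mixed cages with the default tournament roster.
    """
    scenario = SimScenario(seed=seed)
    roster = build_default_roster(scenario.design)
    design = replace(scenario.design, tournaments=default_tournament_roster(roster))
    return replace(scenario, design=design)


def null_scenario(seed: int = 0) -> SimScenario:
    """A fully exchangeable null: every contest an independent fair coin.

    All genotype effects are removed *and* all sources of persistent or
    evolving individual differences are switched off (no strength
    spread, no winner/loser updating, no volatility, no lock-in).  This
    is the scenario under which the genotype chi-square's independence
    assumption holds exactly, so its type-I error rate is nominal; any
    persistent strength heterogeneity would overdisperse win counts
    across a pair's repeated sessions and inflate the test.
    """
    scenario = SimScenario(
        seed=seed,
        theta0_wt=0.0,
        theta0_ko=0.0,
        sigma_theta=0.0,
        delta_win=0.0,
        delta_loss=0.0,
        volatility_wt=0.0,
        volatility_ko=0.0,
        volatility_spread_wt=0.0,
        volatility_spread_ko=0.0,
        p_lock_ko=0.0,
    )
    roster = build_default_roster(scenario.design)
    design = replace(scenario.design, tournaments=default_tournament_roster(roster))
    return replace(scenario, design=design)
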