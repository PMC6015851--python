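"""End-to-end orchestration: records in, ranked tables and tests out.

``run_phase1_analysis`` takes trial records (real or simulated) plus a
roster and produces session rankings, per-rat stability profiles, the
genotype contrasts (mixed-cage win chi-square and rank t-test,
single-line variance/stability t-tests) and the split-half
correlations.  ``run_phase2_analysis`` adds the tournament
cross-tabulations by genotype and by prior rank class.  Every policy
choice is carried in a :class:`RunConfig` whose defaults equal the
documented analysis conventions, and is echoed into a provenance JSON
next to any files written.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .contest_io import CageType, Genotype, Phase, Roster, TrialRecord
from .metrics import (
    DEFAULT_SUBGROUP_THRESHOLDS,
    StabilityProfile,
    Subgroup,
    profiles_table,
    stability_profiles,
)
from .ranking import (
    PairSessionOutcome,
    RankTrajectory,
    SessionRanking,
    rank_study,
    ranking_table,
    score_pair_session,
)
from .stats import CorrelationResult, MeanContrast, WinContrast, chi2_even_split, pearson, two_sample_t
from .tournaments import (
    GENOTYPE_FILTERS,
    CrossTab,
    RankClassTabs,
    assign_rank_class,
    genotype_crosstab,
    phase2_contests,
    rank_class_crosstab,
)

__all__ = [
    "RunConfig",
    "Phase1Results",
    "Phase2Results",
    "run_phase1_analysis",
    "run_phase2_analysis",
    "phase1_phenotypes",
]


@dataclass(frozen=True)
class RunConfig:
    """All tunable policy choices of the pipeline, with their defaults."""

    seed: int = 0
    split: int = 5
    renormalize: str = "half"
    subgroup_thresholds: tuple[float, float] = DEFAULT_SUBGROUP_THRESHOLDS
    rank_class_policy: str = "final"
    count: str = "contests"
    rank_contrast_unit: str = "rat_session"

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Phase1Results:
    rankings: dict[str, list[SessionRanking]]
    trajectories: dict[str, RankTrajectory]
    profiles: dict[str, StabilityProfile]
    contrasts: dict[str, WinContrast | MeanContrast]
    correlations: dict[str, CorrelationResult | None]
    subgroup_counts: dict[str, dict[str, int]]
    mixed_contest_wins: tuple[int, int]


@dataclass
class Phase2Results:
    genotype_tabs: dict[str, CrossTab | None]
    rank_class_tabs: RankClassTabs
    rank_classes: dict[str, str]
    n_contests: int


def _mixed_genotype_wins(
    records: Sequence[TrialRecord], roster: Roster, count: str
) -> tuple[int, int]:
    """WT and KO win counts over cross-genotype contests in mixed cages."""
    blocks: dict[tuple, list[TrialRecord]] = defaultdict(list)
    for rec in records:
        if rec.phase is not Phase.I:
            continue
        if roster.cage_type_of(rec.cage_a) is not CageType.mixed:
            continue
        if roster.genotype_of(rec.rat_a) is roster.genotype_of(rec.rat_b):
            continue
        blocks[(rec.cage_a, rec.session, rec.pair)].append(rec)
    wins = {Genotype.WT: 0, Genotype.KO: 0}
    for trials in blocks.values():
        outcome = score_pair_session(trials)
        if count == "contests":
            wins[roster.genotype_of(outcome.session_winner)] += 1
        else:
            for rat, w in outcome.wins.items():
                wins[roster.genotype_of(rat)] += w
    return wins[Genotype.WT], wins[Genotype.KO]


def _group_values(
    profiles: Mapping[str, StabilityProfile],
    roster: Roster,
    cage_types: set[CageType],
    genotype: Genotype,
    attr: str,
) -> list[float]:
    return [
        getattr(profiles[rat], attr)
        for rat in sorted(profiles)
        if roster.rats[rat].genotype is genotype
        and roster.cage_type_of(roster.rats[rat].cage_id) in cage_types
    ]


def run_phase1_analysis(
    records: Sequence[TrialRecord],
    roster: Roster,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> Phase1Results:
    """The complete within-cage analysis.

    Rankings and trajectories feed the variability metrics; genotype is
    contrasted via the mixed-cage win chi-square, the mixed-cage rank
    t-test (rat-session units by default, 140 + 140 at the standard
    design), and single-line variance/stability t-tests; split-half
    Pearson correlations are computed per cage-type x genotype group
    (``None`` where the correlation is undefined, e.g. every wild-type
    rat perfectly stable in both halves).
    """
    rankings, trajectories = rank_study(records)
    complete = {r: t for r, t in trajectories.items() if t.complete}
    profiles = stability_profiles(
        complete,
        split=config.split,
        thresholds=config.subgroup_thresholds,
        renormalize=config.renormalize,
    )

    contrasts: dict[str, WinContrast | MeanContrast] = {}
    wt_wins, ko_wins = _mixed_genotype_wins(records, roster, config.count)
    if wt_wins + ko_wins > 0:
        contrasts["mixed_genotype_wins"] = chi2_even_split(wt_wins, ko_wins, "WT", "KO")

    # mixed-cage average rank: rat-session observations or per-rat means
    rank_obs: dict[Genotype, list[float]] = {Genotype.WT: [], Genotype.KO: []}
    for cage_id, cage_rankings in rankings.items():
        if roster.cage_type_of(cage_id) is not CageType.mixed:
            continue
        for sr in cage_rankings:
            for rat, rank in sr.ranks.items():
                rank_obs[roster.genotype_of(rat)].append(float(rank))
    if config.rank_contrast_unit == "rat":
        per_rat: dict[Genotype, list[float]] = {Genotype.WT: [], Genotype.KO: []}
        for rat, traj in sorted(complete.items()):
            if roster.cage_type_of(roster.rats[rat].cage_id) is CageType.mixed:
                ranks = [r for r in traj.ranks if r is not None]
                per_rat[roster.genotype_of(rat)].append(sum(ranks) / len(ranks))
        rank_obs = per_rat
    if len(rank_obs[Genotype.WT]) >= 2 and len(rank_obs[Genotype.KO]) >= 2:
        contrasts["mixed_rank_t"] = two_sample_t(
            rank_obs[Genotype.WT], rank_obs[Genotype.KO]
        )

    single = {CageType.WT_only, CageType.KO_only}
    for attr, name in (
        ("variance_pct", "single_variance_t"),
        ("stability_pct", "single_stability_t"),
    ):
        wt_vals = _group_values(profiles, roster, single, Genotype.WT, attr)
        ko_vals = _group_values(profiles, roster, single, Genotype.KO, attr)
        if len(wt_vals) >= 2 and len(ko_vals) >= 2:
            contrasts[name] = two_sample_t(wt_vals, ko_vals)

    correlations: dict[str, CorrelationResult | None] = {}
    all_types = single | {CageType.mixed}
    groups = {
        "single_WT": (single, Genotype.WT),
        "single_KO": (single, Genotype.KO),
        "mixed_WT": ({CageType.mixed}, Genotype.WT),
        "mixed_KO": ({CageType.mixed}, Genotype.KO),
        "all_WT": (all_types, Genotype.WT),
        "all_KO": (all_types, Genotype.KO),
    }
    for gname, (ctypes, genotype) in groups.items():
        for metric in ("stability_pct", "variance_pct"):
            first = _group_values(profiles, roster, ctypes, genotype, f"{metric}_first")
            second = _group_values(profiles, roster, ctypes, genotype, f"{metric}_second")
            key = f"{metric.removesuffix('_pct')}_split_{gname}"
            try:
                correlations[key] = pearson(first, second)
            except ValueError:
                correlations[key] = None

    subgroup_counts: dict[str, dict[str, int]] = {}
    for gname, (ctypes, genotype) in groups.items():
        members = [
            rat
            for rat in sorted(profiles)
            if roster.rats[rat].genotype is genotype
            and roster.cage_type_of(roster.rats[rat].cage_id) in ctypes
        ]
        subgroup_counts[gname] = {
            sg.value: sum(1 for r in members if profiles[r].subgroup is sg)
            for sg in Subgroup
        }

    results = Phase1Results(
        rankings=rankings,
        trajectories=trajectories,
        profiles=profiles,
        contrasts=contrasts,
        correlations=correlations,
        subgroup_counts=subgroup_counts,
        mixed_contest_wins=(wt_wins, ko_wins),
    )
    if outdir is not None:
        _write_phase1(results, roster, config, Path(outdir))
    return results


def run_phase2_analysis(
    records: Sequence[TrialRecord],
    roster: Roster,
    phase1: Phase1Results,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> Phase2Results:
    """The tournament re-analyses (by genotype, by prior rank class)."""
    complete = {r: t for r, t in phase1.trajectories.items() if t.complete}
    rank_classes = assign_rank_class(complete, policy=config.rank_class_policy)
    contests = phase2_contests(records, roster, rank_classes)
    genotype_tabs: dict[str, CrossTab | None] = {}
    for cage_filter in GENOTYPE_FILTERS:
        try:
            genotype_tabs[cage_filter] = genotype_crosstab(
                contests, roster, cage_filter, count=config.count
            )
        except ValueError:
            genotype_tabs[cage_filter] = None
    tabs = rank_class_crosstab(contests, count=config.count)
    results = Phase2Results(
        genotype_tabs=genotype_tabs,
        rank_class_tabs=tabs,
        rank_classes={r: c.value for r, c in rank_classes.items()},
        n_contests=len(contests),
    )
    if outdir is not None:
        _write_phase2(results, config, Path(outdir))
    return results


def phase1_phenotypes(results: Phase1Results, roster: Roster) -> dict[str, bool]:
    """Did the analysis recover the four qualitative phase-I phenotypes?

    1. wild-type dominance in mixed cages (chi-square p < 0.05 in the
       WT direction);
    2. higher knockout rank variance in single-line cages (t-test
       p < 0.05 in the KO direction);
    3. positive split-half stability correlation across wild-type rats
       (pooling housings: the trait claim — early stability predicts
       late stability — holds in both single-line and mixed cages, and
       with only four rank transitions per half the per-housing
       correlation test is underpowered by design, so the indicator is
       directional over all wild-types rather than a significance call
       in one housing);
    4. bimodal knockout stability in mixed cages: at least two
       hyper-stable and two hyper-unstable knockouts.
    """
    out: dict[str, bool] = {}
    chi = results.contrasts.get("mixed_genotype_wins")
    out["wt_mixed_dominance"] = bool(
        chi is not None and chi.p < 0.05 and chi.wins_a > chi.wins_b
    )
    t = results.contrasts.get("single_variance_t")
    out["ko_higher_variance"] = bool(
        t is not None and t.p < 0.05 and t.mean_b > t.mean_a
    )
    corr = results.correlations.get("stability_split_all_WT")
    out["wt_stability_correlation"] = bool(corr is not None and corr.r > 0)
    ko_mixed = results.subgroup_counts.get("mixed_KO", {})
    out["ko_bimodal_stability"] = bool(
        ko_mixed.get("hyper_stable", 0) >= 2 and ko_mixed.get("hyper_unstable", 0) >= 2
    )
    return out


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------


def _contrast_rows(contrasts: Mapping[str, WinContrast | MeanContrast]) -> pd.DataFrame:
    rows = []
    for name in sorted(contrasts):
        c = contrasts[name]
        if isinstance(c, WinContrast):
            rows.append(
                {"analysis": name, "statistic": "chi2", "value": c.chi2,
                 "df": c.df, "p": c.p,
                 "detail": f"{c.label_a}={c.wins_a},{c.label_b}={c.wins_b}"}
            )
        else:
            rows.append(
                {"analysis": name, "statistic": "t", "value": c.t,
                 "df": c.df, "p": c.p,
                 "detail": f"mean_a={c.mean_a:.4g},mean_b={c.mean_b:.4g},"
                           f"n_a={c.n_a},n_b={c.n_b}"}
            )
    return pd.DataFrame(rows, columns=["analysis", "statistic", "value", "df", "p", "detail"])


def _write_provenance(config: RunConfig, outdir: Path) -> None:
    doc = {
        "package": "tubetest",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.digest(),
    }
    (outdir / "provenance.json").write_text(json.dumps(doc, indent=2) + "\n")


def _write_phase1(
    results: Phase1Results, roster: Roster, config: RunConfig, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ranking_table(results.rankings).to_csv(outdir / "rankings.csv", index=False)
    profiles_table(results.profiles, roster).to_csv(outdir / "metrics.csv", index=False)
    _contrast_rows(results.contrasts).to_csv(outdir / "contrasts.csv", index=False)
    rows = []
    for name in sorted(results.correlations):
        c = results.correlations[name]
        rows.append(
            {"analysis": name, "n": c.n if c else None, "r": c.r if c else None,
             "p": c.p if c else None, "slope": c.slope if c else None}
        )
    pd.DataFrame(rows, columns=["analysis", "n", "r", "p", "slope"]).to_csv(
        outdir / "correlations.csv", index=False
    )
    _write_provenance(config, outdir)


def _crosstab_rows(tabs: Mapping[str, CrossTab | None]) -> pd.DataFrame:
    rows = []
    for name in sorted(tabs):
        tab = tabs[name]
        if tab is None:
            rows.append({"crosstab": name, "wins": "", "n_contests": 0,
                         "chi2": None, "df": None, "p": None})
            continue
        wins = ",".join(f"{k}={v}" for k, v in tab.wins.items())
        rows.append(
            {"crosstab": name, "wins": wins, "n_contests": tab.n_contests,
             "chi2": tab.chi2.chi2 if tab.chi2 else None,
             "df": tab.chi2.df if tab.chi2 else None,
             "p": tab.chi2.p if tab.chi2 else None}
        )
    return pd.DataFrame(
        rows, columns=["crosstab", "wins", "n_contests", "chi2", "df", "p"]
    )


def _write_phase2(results: Phase2Results, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tabs: dict[str, CrossTab | None] = {
        f"genotype_{k}": v for k, v in results.genotype_tabs.items()
    }
    tabs["rank_high_vs_low"] = results.rank_class_tabs.high_vs_low
    tabs["rank_high_conditional"] = results.rank_class_tabs.high_conditional
    tabs["rank_low_conditional"] = results.rank_class_tabs.low_conditional
    _crosstab_rows(tabs).to_csv(outdir / "crosstabs.csv", index=False)
    pd.DataFrame(
        sorted(results.rank_classes.items()), columns=["rat_id", "rank_class"]
    ).to_csv(outdir / "rank_classes.csv", index=False)
    _write_provenance(config, outdir)
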