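"""Per-rat rank-variability measures.

Two complementary summaries of a rank trajectory (a rat's within-cage
rank 1-4 across sessions):

* **normalized variance** — the sample variance (n-1 divisor) of the
  rank sequence, expressed as a percentage of the maximum sample
  variance any sequence of that length and rank range can attain.  For
  10 sessions of ranks 1-4 the maximum is 2.5 (five sessions at rank 1
  and five at rank 4), so an alternating 1,4,1,4,... trajectory scores
  100%.
* **stability** — the fraction of consecutive-session transitions in
  which the rat retained its rank, without regard to the size of any
  change; over 10 sessions there are 9 transitions, so 9 retentions is
  100%.

Both are also computed separately for the first and second half of
testing (sessions 1-5 vs 6-10 by default), each half normalized to its
own length, to ask whether early variability predicts late variability.
Animals with extreme late-half stability are flagged as hyper-stable or
hyper-unstable — knockout rats characteristically split bimodally into
these two groups while wild-types cluster at intermediate-to-high
stability.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .contest_io import Roster
from .ranking import RankTrajectory

__all__ = [
    "Subgroup",
    "StabilityProfile",
    "max_rank_variance",
    "normalized_variance",
    "stability",
    "split_session_metrics",
    "classify_subgroups",
    "stability_profiles",
    "profiles_table",
]

#: default hyper-stable / hyper-unstable cut-offs (%) on late-half stability
DEFAULT_SUBGROUP_THRESHOLDS = (75.0, 25.0)

#: default rank range inside a four-rat cage
DEFAULT_RANK_RANGE = (1, 4)


class Subgroup(str, enum.Enum):
    hyper_stable = "hyper_stable"
    hyper_unstable = "hyper_unstable"
    intermediate = "intermediate"


@dataclass(frozen=True)
class StabilityProfile:
    """All variability summaries for one rat."""

    rat_id: str
    variance_pct: float
    stability_pct: float
    variance_pct_first: float
    variance_pct_second: float
    stability_pct_first: float
    stability_pct_second: float
    subgroup: Subgroup


def _ranks(trajectory: RankTrajectory | Sequence[int]) -> np.ndarray:
    ranks = trajectory.ranks if isinstance(trajectory, RankTrajectory) else trajectory
    if any(r is None for r in ranks):
        raise ValueError("trajectory has gaps; variability metrics need complete data")
    return np.asarray(ranks, dtype=float)


def max_rank_variance(n_sessions: int, rank_range: tuple[int, int] = DEFAULT_RANK_RANGE) -> float:
    """Maximum sample variance of a length-n sequence with bounded entries.

    An extremal sequence puts every entry at one of the two endpoints of
    the range (moving any interior value to the farther endpoint cannot
    decrease the sum of squared deviations), so the maximum is found by
    scanning the split k/(n-k) between the endpoints:

        var(k) = k (n-k) (hi-lo)^2 / (n (n-1))

    maximized at the most even split.  For n=10 and ranks 1-4 this gives
    2.5, the normalization constant of the percentage-variance metric.
    """
    if n_sessions < 2:
        raise ValueError("need at least two sessions for a variance")
    lo, hi = rank_range
    if hi < lo:
        raise ValueError(f"bad rank range {rank_range}")
    span = float(hi - lo)
    if span == 0.0:
        return 0.0
    n = n_sessions
    return max(
        k * (n - k) * span**2 / (n * (n - 1)) for k in range(1, n)
    )


def normalized_variance(
    trajectory: RankTrajectory | Sequence[int],
    rank_range: tuple[int, int] = DEFAULT_RANK_RANGE,
) -> float:
    """Sample variance of the rank sequence as % of the attainable maximum."""
    ranks = _ranks(trajectory)
    if ranks.size < 2:
        raise ValueError("need at least two sessions")
    vmax = max_rank_variance(ranks.size, rank_range)
    if vmax == 0.0:
        return 0.0
    return float(np.var(ranks, ddof=1) / vmax * 100.0)


def stability(trajectory: RankTrajectory | Sequence[int]) -> float:
    """Percentage of consecutive-session transitions with rank retained."""
    ranks = _ranks(trajectory)
    if ranks.size < 2:
        raise ValueError("need at least two sessions")
    retained = np.sum(np.diff(ranks) == 0)
    return float(retained / (ranks.size - 1) * 100.0)


def split_session_metrics(
    trajectory: RankTrajectory | Sequence[int],
    split: int = 5,
    rank_range: tuple[int, int] = DEFAULT_RANK_RANGE,
    renormalize: str = "half",
) -> dict[str, tuple[float, float]]:
    """Variance and stability computed separately for each half.

    ``split`` is the last session of the first half (1-based).  With
    ``renormalize="half"`` (default) each half's variance is scaled by
    the maximum for its own length; ``renormalize="full"`` keeps the
    full-trajectory maximum as the reference.  Stability always uses the
    half's own transition count (4 per half of 5 sessions).
    """
    ranks = _ranks(trajectory)
    first, second = ranks[:split], ranks[split:]
    if first.size < 2 or second.size < 2:
        raise ValueError(f"split at {split} leaves a half shorter than 2 sessions")
    if renormalize == "half":
        vmax_first = max_rank_variance(first.size, rank_range)
        vmax_second = max_rank_variance(second.size, rank_range)
    elif renormalize == "full":
        vmax_first = vmax_second = max_rank_variance(ranks.size, rank_range)
    else:
        raise ValueError(f"renormalize must be 'half' or 'full', got {renormalize!r}")
    var_first = float(np.var(first, ddof=1) / vmax_first * 100.0) if vmax_first else 0.0
    var_second = (
        float(np.var(second, ddof=1) / vmax_second * 100.0) if vmax_second else 0.0
    )
    return {
        "variance_pct": (var_first, var_second),
        "stability_pct": (stability(first), stability(second)),
    }


def classify_subgroups(
    late_stability: Mapping[str, float],
    thresholds: tuple[float, float] = DEFAULT_SUBGROUP_THRESHOLDS,
) -> tuple[dict[str, Subgroup], dict[Subgroup, int]]:
    """Label rats by late-half stability.

    ``thresholds = (hi, lo)``: stability >= hi -> hyper-stable,
    <= lo -> hyper-unstable, otherwise intermediate.  The cut-offs are a
    policy choice (the bimodal split is an empirical observation with no
    canonical boundary) and are therefore reported with the counts.
    """
    hi, lo = thresholds
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError(f"thresholds must satisfy 0 <= lo < hi <= 100, got {thresholds}")
    labels = {}
    for rat, value in late_stability.items():
        if not (0.0 <= value <= 100.0):
            raise ValueError(f"stability {value} for {rat} outside [0, 100]")
        if value >= hi:
            labels[rat] = Subgroup.hyper_stable
        elif value <= lo:
            labels[rat] = Subgroup.hyper_unstable
        else:
            labels[rat] = Subgroup.intermediate
    counts = {sg: sum(1 for v in labels.values() if v is sg) for sg in Subgroup}
    return labels, counts


def stability_profiles(
    trajectories: Mapping[str, RankTrajectory],
    split: int = 5,
    rank_range: tuple[int, int] = DEFAULT_RANK_RANGE,
    thresholds: tuple[float, float] = DEFAULT_SUBGROUP_THRESHOLDS,
    renormalize: str = "half",
) -> dict[str, StabilityProfile]:
    """Full per-rat variability profile for a cohort of trajectories."""
    halves = {
        rat: split_session_metrics(traj, split, rank_range, renormalize)
        for rat, traj in trajectories.items()
    }
    late = {rat: h["stability_pct"][1] for rat, h in halves.items()}
    labels, _counts = classify_subgroups(late, thresholds)
    return {
        rat: StabilityProfile(
            rat_id=rat,
            variance_pct=normalized_variance(traj, rank_range),
            stability_pct=stability(traj),
            variance_pct_first=halves[rat]["variance_pct"][0],
            variance_pct_second=halves[rat]["variance_pct"][1],
            stability_pct_first=halves[rat]["stability_pct"][0],
            stability_pct_second=halves[rat]["stability_pct"][1],
            subgroup=labels[rat],
        )
        for rat, traj in trajectories.items()
    }


def profiles_table(
    profiles: Mapping[str, StabilityProfile], roster: Roster | None = None
) -> pd.DataFrame:
    """Tidy per-rat metrics table, annotated with genotype/cage if known."""
    rows = []
    for rat in sorted(profiles):
        p = profiles[rat]
        row = {
            "rat_id": rat,
            "variance_pct": p.variance_pct,
            "stability_pct": p.stability_pct,
            "variance_pct_first": p.variance_pct_first,
            "variance_pct_second": p.variance_pct_second,
            "stability_pct_first": p.stability_pct_first,
            "stability_pct_second": p.stability_pct_second,
            "subgroup": p.subgroup.value,
        }
        if roster is not None and rat in roster.rats:
            row["genotype"] = roster.rats[rat].genotype.value
            row["cage_id"] = roster.rats[rat].cage_id
            row["cage_type"] = roster.cage_type_of(roster.rats[rat].cage_id).value
        rows.append(row)
    return pd.DataFrame(rows)
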