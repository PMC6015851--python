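"""Independent brute-force oracle for the session ranking policy.

Written from the policy statement, not from the implementation: a
candidate ordering of the four rats is valid iff points are
non-increasing along it and every equal-point group is internally
ordered by the first applicable rule — strict head-to-head order,
then session trial wins, then rat id.  The oracle enumerates all 24
permutations and returns the unique valid one.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

from tubetest.ranking import PairSessionOutcome


def _group_order_ok(
    group: Sequence[str],
    by_pair: Mapping[tuple[str, str], PairSessionOutcome],
    trial_wins: Mapping[str, int],
) -> bool:
    """Does this ordering of an equal-point group follow the tie policy?"""
    h2h = {r: 0 for r in group}
    complete = True
    for x, y in itertools.combinations(sorted(group), 2):
        outcome = by_pair.get((x, y))
        if outcome is None:
            complete = False
            break
        h2h[outcome.session_winner] += 1
    if complete and len(set(h2h.values())) == len(group):
        return all(h2h[group[i]] > h2h[group[i + 1]] for i in range(len(group) - 1))
    if len({trial_wins[r] for r in group}) == len(group):
        return all(
            trial_wins[group[i]] > trial_wins[group[i + 1]]
            for i in range(len(group) - 1)
        )
    keys = [(-trial_wins[r], r) for r in group]
    return keys == sorted(keys)


def oracle_rank(
    points: Mapping[str, int], outcomes: Sequence[PairSessionOutcome]
) -> dict[str, int]:
    """Rank a cage-session by exhaustive enumeration of permutations."""
    by_pair = {o.pair: o for o in outcomes}
    trial_wins: dict[str, int] = {r: 0 for r in points}
    for o in outcomes:
        for rat, w in o.wins.items():
            trial_wins[rat] += w

    valid = []
    for perm in itertools.permutations(sorted(points)):
        pts = [points[r] for r in perm]
        if any(pts[i] < pts[i + 1] for i in range(len(pts) - 1)):
            continue
        ok = True
        for value in set(pts):
            group = [r for r in perm if points[r] == value]
            if len(group) > 1 and not _group_order_ok(group, by_pair, trial_wins):
                ok = False
                break
        if ok:
            valid.append(perm)
    assert len(valid) == 1, f"policy is not total/deterministic: {valid}"
    return {rat: i + 1 for i, rat in enumerate(valid[0])}
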