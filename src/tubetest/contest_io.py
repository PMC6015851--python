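"""Contest-record data model, CSV round-trip, and design validation.

The tube test is a dyadic dominance assay: two rats meet head-on in a
tube and the one that forces or induces the other to retreat (reaches
the far entrance barrier) wins.  A study consists of home cages of four
rats tested in two phases: phase I runs every within-cage pair (6 pairs)
for a 5-trial block per session across repeated sessions; phase II pits
whole cages against each other in round-robin tournaments (16 cross-cage
pairs, 5 trials per pair, repeated across sessions).

Everything downstream (ranking, stability metrics, tournaments) consumes
the long-format trial records defined here.  The on-disk dialect is a
plain UTF-8 CSV with one row per trial::

    phase,session,cage_a,rat_a,cage_b,rat_b,trial_index,winner,latency_s,start_side

Pairs are unordered; records are stored canonically with
``rat_a < rat_b`` (lexicographic) so that files diff deterministically.
Latency is retained for completeness but never used in inference: it is
too variable within and between animals to be a useful dominance
measure.
"""

from __future__ import annotations

import enum
import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Genotype",
    "CageType",
    "Phase",
    "StartSide",
    "Rat",
    "Cage",
    "TrialRecord",
    "StudyDesign",
    "Roster",
    "ValidationIssue",
    "ValidationReport",
    "CSV_COLUMNS",
    "read_contests",
    "write_contests",
    "validate_design",
    "load_design",
    "save_design",
]


class Genotype(str, enum.Enum):
    WT = "WT"
    KO = "KO"


class CageType(str, enum.Enum):
    WT_only = "WT_only"
    KO_only = "KO_only"
    mixed = "mixed"


class Phase(str, enum.Enum):
    I = "I"
    II = "II"


class StartSide(str, enum.Enum):
    left = "left"
    right = "right"


#: canonical column order of the contest CSV
CSV_COLUMNS = (
    "phase",
    "session",
    "cage_a",
    "rat_a",
    "cage_b",
    "rat_b",
    "trial_index",
    "winner",
    "latency_s",
    "start_side",
)

_FLIP_SIDE = {StartSide.left: StartSide.right, StartSide.right: StartSide.left}


@dataclass(frozen=True)
class Rat:
    """One study subject; genotype is immutable for its lifetime."""

    rat_id: str
    cage_id: str
    genotype: Genotype
    cohort: int = 1
    weight_g: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genotype", Genotype(self.genotype))
        if self.weight_g is not None and not (100.0 <= self.weight_g <= 1000.0):
            raise ValueError(
                f"rat {self.rat_id}: weight {self.weight_g} g outside plausible "
                "adult-rat range [100, 1000]"
            )


@dataclass(frozen=True)
class Cage:
    """A home cage; the standard design houses exactly four rats per cage."""

    cage_id: str
    cage_type: CageType
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cage_type", CageType(self.cage_type))
        object.__setattr__(self, "members", tuple(sorted(self.members)))
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"cage {self.cage_id}: duplicate member ids")


@dataclass(frozen=True)
class TrialRecord:
    """One tube-test run: two rats, one winner.

    The pair is unordered; construction canonicalises the record so that
    ``rat_a < rat_b`` lexicographically, swapping cage labels and
    flipping ``start_side`` along with the rats.  Phase I trials are
    within-cage (``cage_a == cage_b``); phase II trials are between
    cages.
    """

    phase: Phase
    session: int
    cage_a: str
    rat_a: str
    cage_b: str
    rat_b: str
    trial_index: int
    winner: str
    latency_s: float | None = None
    start_side: StartSide | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        side = StartSide(self.start_side) if self.start_side is not None else None
        if self.rat_a == self.rat_b:
            raise ValueError(f"trial pairs rat {self.rat_a} with itself")
        if self.rat_a > self.rat_b:
            ra, rb = self.rat_b, self.rat_a
            ca, cb = self.cage_b, self.cage_a
            object.__setattr__(self, "rat_a", ra)
            object.__setattr__(self, "rat_b", rb)
            object.__setattr__(self, "cage_a", ca)
            object.__setattr__(self, "cage_b", cb)
            if side is not None:
                side = _FLIP_SIDE[side]
        object.__setattr__(self, "start_side", side)
        if self.winner not in (self.rat_a, self.rat_b):
            raise ValueError(
                f"winner {self.winner!r} is not a member of pair "
                f"({self.rat_a}, {self.rat_b})"
            )
        if self.session < 1:
            raise ValueError(f"session must be >= 1, got {self.session}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.latency_s is not None and self.latency_s <= 0:
            raise ValueError(f"latency must be positive, got {self.latency_s}")
        if self.phase is Phase.I and self.cage_a != self.cage_b:
            raise ValueError(
                f"phase I trial pairs rats from different cages "
                f"({self.cage_a}, {self.cage_b})"
            )
        if self.phase is Phase.II and self.cage_a == self.cage_b:
            raise ValueError(f"phase II trial pairs cage {self.cage_a} with itself")

    @property
    def pair(self) -> tuple[str, str]:
        """The canonical (sorted) rat-id pair."""
        return (self.rat_a, self.rat_b)

    @property
    def loser(self) -> str:
        return self.rat_b if self.winner == self.rat_a else self.rat_a


@dataclass(frozen=True)
class StudyDesign:
    """Counts and block structure of the experiment.

    The default mirrors the standard two-phase design: 3 WT-only, 4
    KO-only and 7 mixed cages (4 rats each, 56 rats in total), 10 phase-I
    sessions, and 5 trials per pair per session.  ``tournaments`` lists
    phase-II cage pairings as ``(cage_a, cage_b, n_sessions)``.
    """

    n_cages_by_type: Mapping[CageType, int] = field(
        default_factory=lambda: {
            CageType.WT_only: 3,
            CageType.KO_only: 4,
            CageType.mixed: 7,
        }
    )
    sessions_phase1: int = 10
    trials_per_pair: int = 5
    tournaments: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        counts = {CageType(k): int(v) for k, v in self.n_cages_by_type.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("cage counts must be non-negative")
        object.__setattr__(self, "n_cages_by_type", counts)
        object.__setattr__(
            self, "tournaments", tuple((a, b, int(n)) for a, b, n in self.tournaments)
        )
        if self.trials_per_pair < 1 or self.trials_per_pair % 2 == 0:
            raise ValueError("trials_per_pair must be a positive odd number")

    @property
    def n_cages(self) -> int:
        return sum(self.n_cages_by_type.values())

    @property
    def n_rats(self) -> int:
        return 4 * self.n_cages


@dataclass
class Roster:
    """Lookup tables for the study population."""

    rats: dict[str, Rat]
    cages: dict[str, Cage]

    def genotype_of(self, rat_id: str) -> Genotype:
        return self.rats[rat_id].genotype

    def cage_of(self, rat_id: str) -> str:
        return self.rats[rat_id].cage_id

    def cage_type_of(self, cage_id: str) -> CageType:
        return self.cages[cage_id].cage_type

    def rats_in(self, cage_id: str) -> tuple[str, ...]:
        return self.cages[cage_id].members


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str
    line: int | None = None

    def __str__(self) -> str:
        loc = f"line {self.line}: " if self.line is not None else ""
        return f"[{self.code}] {loc}{self.message}"


@dataclass
class ValidationReport:
    """Accumulated integrity problems; a report, not an exception."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, code: str, message: str, line: int | None = None) -> None:
        self.issues.append(ValidationIssue(code, message, line))

    @property
    def ok(self) -> bool:
        return not self.issues

    @property
    def n_violations(self) -> int:
        return len(self.issues)

    def __str__(self) -> str:
        if self.ok:
            return "OK: no violations"
        lines = [f"{len(self.issues)} violation(s):"]
        lines += [f"  {issue}" for issue in self.issues]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------


class SchemaError(ValueError):
    """The file header does not match the documented contest schema."""


def read_contests(path: str | Path) -> tuple[list[TrialRecord], ValidationReport]:
    """Read a contest CSV into trial records.

    Every parseable row becomes a :class:`TrialRecord`; malformed rows
    (winner outside the pair, bad numbers, duplicate trials) are
    collected in the returned report with their 1-based line number.
    A missing column is unrecoverable and raises :class:`SchemaError`.
    Row order is preserved.
    """
    path = Path(path)
    report = ValidationReport()
    records: list[TrialRecord] = []
    seen: set[tuple] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        import csv

        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = TrialRecord(
                    phase=row["phase"],
                    session=int(row["session"]),
                    cage_a=row["cage_a"],
                    rat_a=row["rat_a"],
                    cage_b=row["cage_b"],
                    rat_b=row["rat_b"],
                    trial_index=int(row["trial_index"]),
                    winner=row["winner"],
                    latency_s=float(row["latency_s"]) if row["latency_s"] else None,
                    start_side=row["start_side"] or None,
                )
            except (ValueError, KeyError) as exc:
                report.add("row_error", str(exc), line=lineno)
                continue
            key = (rec.phase, rec.session, rec.pair, rec.trial_index)
            if key in seen:
                report.add(
                    "duplicate_trial",
                    f"duplicate trial {rec.pair} session {rec.session} "
                    f"trial {rec.trial_index}",
                    line=lineno,
                )
                continue
            seen.add(key)
            records.append(rec)
    return records, report


def write_contests(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write records as CSV with the documented column order.

    Missing latency / start side are written as empty fields (absent is
    not zero); the round trip through :func:`read_contests` is lossless.
    """
    import csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.phase.value,
                    rec.session,
                    rec.cage_a,
                    rec.rat_a,
                    rec.cage_b,
                    rec.rat_b,
                    rec.trial_index,
                    rec.winner,
                    "" if rec.latency_s is None else repr(rec.latency_s),
                    "" if rec.start_side is None else rec.start_side.value,
                ]
            )


# ---------------------------------------------------------------------------
# design validation
# ---------------------------------------------------------------------------

_COMPOSITION = {
    CageType.WT_only: Counter({Genotype.WT: 4}),
    CageType.KO_only: Counter({Genotype.KO: 4}),
    CageType.mixed: Counter({Genotype.WT: 2, Genotype.KO: 2}),
}


def validate_design(
    records: Sequence[TrialRecord],
    design: StudyDesign,
    roster: Roster,
) -> ValidationReport:
    """Check experimental-design integrity of a parsed record set.

    Reports (never raises) on: cage counts per type differing from the
    design, cage composition violations (member count, genotype mix),
    rats appearing in records under the wrong cage, phase-I pair-sessions
    that are missing or short of ``trials_per_pair`` trials, and
    phase-II tournaments with missing pair-sessions.
    """
    report = ValidationReport()

    counts = Counter(c.cage_type for c in roster.cages.values())
    for ctype, expected in design.n_cages_by_type.items():
        if counts.get(ctype, 0) != expected:
            report.add(
                "cage_count",
                f"{ctype.value}: expected {expected} cages, found {counts.get(ctype, 0)}",
            )

    for cage in roster.cages.values():
        if len(cage.members) != 4:
            report.add(
                "cage_size",
                f"cage {cage.cage_id}: {len(cage.members)} members, expected 4",
            )
        member_genotypes = Counter(
            roster.rats[r].genotype for r in cage.members if r in roster.rats
        )
        unknown = [r for r in cage.members if r not in roster.rats]
        for r in unknown:
            report.add("unknown_rat", f"cage {cage.cage_id}: member {r} not in roster")
        if not unknown and member_genotypes != _COMPOSITION[cage.cage_type]:
            want = dict(_COMPOSITION[cage.cage_type])
            have = dict(member_genotypes)
            report.add(
                "cage_composition",
                f"cage {cage.cage_id} ({cage.cage_type.value}): genotype mix "
                f"{ {k.value: v for k, v in have.items()} } != required "
                f"{ {k.value: v for k, v in want.items()} }",
            )

    for rec in records:
        for rat, cage in ((rec.rat_a, rec.cage_a), (rec.rat_b, rec.cage_b)):
            if rat in roster.rats and roster.rats[rat].cage_id != cage:
                report.add(
                    "cage_mismatch",
                    f"rat {rat} recorded in cage {cage} but housed in "
                    f"{roster.rats[rat].cage_id}",
                )
                break  # one report per record is enough

    # phase I completeness: every within-cage pair, every session
    trials1 = Counter(
        (rec.cage_a, rec.session, rec.pair)
        for rec in records
        if rec.phase is Phase.I
    )
    for cage in roster.cages.values():
        pairs = list(itertools.combinations(sorted(cage.members), 2))
        for session in range(1, design.sessions_phase1 + 1):
            for pair in pairs:
                n = trials1.get((cage.cage_id, session, pair), 0)
                if n == 0:
                    report.add(
                        "missing_pair_session",
                        f"cage {cage.cage_id} session {session}: pair {pair} untested",
                    )
                elif n != design.trials_per_pair:
                    report.add(
                        "trial_shortfall",
                        f"cage {cage.cage_id} session {session}: pair {pair} has "
                        f"{n} trials, expected {design.trials_per_pair}",
                    )

    # phase II completeness per declared tournament
    trials2 = Counter(
        (frozenset((rec.cage_a, rec.cage_b)), rec.session, rec.pair)
        for rec in records
        if rec.phase is Phase.II
    )
    for cage_a, cage_b, n_sessions in design.tournaments:
        if cage_a not in roster.cages or cage_b not in roster.cages:
            report.add("unknown_cage", f"tournament ({cage_a}, {cage_b}): unknown cage")
            continue
        key = frozenset((cage_a, cage_b))
        cross_pairs = [
            tuple(sorted((ra, rb)))
            for ra in roster.cages[cage_a].members
            for rb in roster.cages[cage_b].members
        ]
        for session in range(1, n_sessions + 1):
            for pair in cross_pairs:
                n = trials2.get((key, session, pair), 0)
                if n == 0:
                    report.add(
                        "missing_pair_session",
                        f"tournament {cage_a}-{cage_b} session {session}: "
                        f"pair {pair} untested",
                    )
                elif n != design.trials_per_pair:
                    report.add(
                        "trial_shortfall",
                        f"tournament {cage_a}-{cage_b} session {session}: pair "
                        f"{pair} has {n} trials, expected {design.trials_per_pair}",
                    )

    return report


# ---------------------------------------------------------------------------
# YAML study-design config
# ---------------------------------------------------------------------------


def load_design(path: str | Path) -> tuple[StudyDesign, Roster]:
    """Load a YAML study-design file naming cages, rats and tournaments."""
    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    ddoc = doc.get("design", {})
    rats = {
        r["rat_id"]: Rat(
            rat_id=r["rat_id"],
            cage_id=r["cage_id"],
            genotype=r["genotype"],
            cohort=int(r.get("cohort", 1)),
            weight_g=r.get("weight_g"),
        )
        for r in doc.get("rats", [])
    }
    cages = {}
    for c in doc.get("cages", []):
        members = tuple(rid for rid, r in rats.items() if r.cage_id == c["cage_id"])
        cages[c["cage_id"]] = Cage(c["cage_id"], c["cage_type"], members)
    tournaments = tuple(
        (t["cage_a"], t["cage_b"], int(t.get("n_sessions", 3)))
        for t in doc.get("tournaments", [])
    )
    design = StudyDesign(
        n_cages_by_type=ddoc.get(
            "n_cages_by_type",
            {ct: sum(1 for c in cages.values() if c.cage_type is ct) for ct in CageType},
        ),
        sessions_phase1=int(ddoc.get("sessions_phase1", 10)),
        trials_per_pair=int(ddoc.get("trials_per_pair", 5)),
        tournaments=tournaments,
    )
    return design, Roster(rats=rats, cages=cages)


def save_design(design: StudyDesign, roster: Roster, path: str | Path) -> None:
    """Write the YAML counterpart of :func:`load_design` (lossless)."""
    doc = {
        "design": {
            "n_cages_by_type": {
                ct.value: n for ct, n in design.n_cages_by_type.items()
            },
            "sessions_phase1": design.sessions_phase1,
            "trials_per_pair": design.trials_per_pair,
        },
        "cages": [
            {"cage_id": c.cage_id, "cage_type": c.cage_type.value}
            for c in sorted(roster.cages.values(), key=lambda c: c.cage_id)
        ],
        "rats": [
            {
                "rat_id": r.rat_id,
                "cage_id": r.cage_id,
                "genotype": r.genotype.value,
                "cohort": r.cohort,
                **({"weight_g": r.weight_g} if r.weight_g is not None else {}),
            }
            for r in sorted(roster.rats.values(), key=lambda r: r.rat_id)
        ],
        "tournaments": [
            {"cage_a": a, "cage_b": b, "n_sessions": n}
            for a, b, n in design.tournaments
        ],
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
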