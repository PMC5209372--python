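"""Domain types, validation and delimited-text I/O for cross-sectional ToM cohorts.

One row per child: age in months, gender, test-administrator id, the ToM
sum-score (0–110) and the five sub-scores it decomposes into — emotion
recognition (max 14), mental/physical distinction (max 44), seeing-leads-to-
knowing (max 3), desires (max 17) and beliefs (max 32).  The interchange
format is a plain UTF-8 CSV with a fixed header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Closed bounds for each scored column.
SUBSCORE_MAXIMA: dict[str, int] = {
    "sub_er": 14,   # emotion recognition
    "sub_mp": 44,   # mental/physical distinction
    "sub_sk": 3,    # seeing leads to knowing
    "sub_des": 17,  # desires
    "sub_bel": 32,  # beliefs
}
SUM_SCORE_MAX = 110
AGE_MIN, AGE_MAX = 36, 143

#: Question structure of the instrument: binary test questions worth one
#: point each, plus justification questions scored 0/1/2.
N_TEST_QUESTIONS = 74
N_JUSTIFICATION_QUESTIONS = 18
JUSTIFICATION_MAX_POINTS = 2

#: Canonical CSV column order.
CSV_COLUMNS = [
    "child_id",
    "age_months",
    "gender",
    "administrator_id",
    "sum_score",
    "sub_er",
    "sub_mp",
    "sub_sk",
    "sub_des",
    "sub_bel",
]

SUBSCORE_COLUMNS = list(SUBSCORE_MAXIMA)


class CohortValidationError(ValueError):
    """Raised when a record or file violates the score-structure invariants."""


@dataclass(frozen=True)
class ChildRecord:
    """A single child's cross-sectional ToM measurement."""

    child_id: str
    age_months: int
    gender: str  # "M" or "F"
    administrator_id: int
    sum_score: int
    sub_er: int
    sub_mp: int
    sub_sk: int
    sub_des: int
    sub_bel: int

    def subscores(self) -> tuple[int, int, int, int, int]:
        return (self.sub_er, self.sub_mp, self.sub_sk, self.sub_des, self.sub_bel)

    def validate(self) -> None:
        """Raise :class:`CohortValidationError` if any invariant is violated."""
        problems = validate_record(self)
        if problems:
            raise CohortValidationError(
                f"record {self.child_id!r}: " + "; ".join(problems)
            )


def validate_record(rec: ChildRecord) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid)."""
    problems: list[str] = []
    if not (AGE_MIN <= rec.age_months <= AGE_MAX):
        problems.append(
            f"age_months={rec.age_months} outside [{AGE_MIN}, {AGE_MAX}]"
        )
    if rec.gender not in ("M", "F"):
        problems.append(f"gender={rec.gender!r} not in {{'M', 'F'}}")
    if not (1 <= rec.administrator_id <= 8):
        problems.append(f"administrator_id={rec.administrator_id} outside [1, 8]")
    if not (0 <= rec.sum_score <= SUM_SCORE_MAX):
        problems.append(f"sum_score={rec.sum_score} outside [0, {SUM_SCORE_MAX}]")
    for name, maximum in SUBSCORE_MAXIMA.items():
        value = getattr(rec, name)
        if not (0 <= value <= maximum):
            problems.append(f"{name}={value} outside [0, {maximum}]")
    if sum(rec.subscores()) != rec.sum_score:
        problems.append(
            f"sub-scores sum to {sum(rec.subscores())} but sum_score={rec.sum_score}"
        )
    return problems


@dataclass
class Cohort:
    """An ordered collection of validated child records.

    ``provenance`` is one of ``"empirical"``, ``"synthetic"`` or
    ``"null-simulated"``; synthetic cohorts record the generator seed.
    """

    records: list[ChildRecord]
    label: str = ""
    provenance: str = "empirical"
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.child_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate child_id values in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        errors = []
        for i, rec in enumerate(self.records):
            problems = validate_record(rec)
            if problems:
                errors.append(f"row {i} ({rec.child_id!r}): " + "; ".join(problems))
        if errors:
            raise CohortValidationError("\n".join(errors))

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame in canonical column order."""
        return pd.DataFrame(
            [[getattr(r, c) for c in CSV_COLUMNS] for r in self.records],
            columns=CSV_COLUMNS,
        )

    def ages(self):
        return self.to_frame()["age_months"].to_numpy()

    def scores(self, column: str = "sum_score"):
        return self.to_frame()[column].to_numpy()

    def subset(self, mask: Sequence[bool], label_suffix: str = "") -> "Cohort":
        kept = [r for r, keep in zip(self.records, mask) if keep]
        return Cohort(
            records=kept,
            label=self.label + label_suffix,
            provenance=self.provenance,
            seed=self.seed,
        )

    def by_gender(self, gender: str) -> "Cohort":
        return self.subset(
            [r.gender == gender for r in self.records], f"/gender={gender}"
        )

    def administrators(self) -> list[int]:
        return sorted({r.administrator_id for r in self.records})

    def drop_administrator(self, administrator_id: int) -> "Cohort":
        return self.subset(
            [r.administrator_id != administrator_id for r in self.records],
            f"/minus-admin-{administrator_id}",
        )

    def with_records(self, records: Iterable[ChildRecord]) -> "Cohort":
        return replace(self, records=list(records))


#: Year bins of the study design (month ranges, closed on both ends).
DESIGN_BINS: list[tuple[int, int]] = [
    (36, 47),    # 3 y
    (48, 59),    # 4 y
    (60, 71),    # 5 y
    (72, 83),    # 6 y
    (84, 95),    # 7 y
    (96, 119),   # 8–9 y
    (120, 143),  # 10–11 y
]

DESIGN_BIN_LABELS = ["3", "4", "5", "6", "7", "8-9", "10-11"]

#: Per-bin (boys, girls) counts of the reference study design (N = 324).
DEFAULT_DESIGN_COUNTS: list[tuple[int, int]] = [
    (32, 29),
    (31, 24),
    (31, 32),
    (31, 26),
    (15, 16),
    (14, 12),
    (13, 18),
]


@dataclass(frozen=True)
class AgeGenderDesign:
    """Counts of boys and girls per age bin (months, closed ranges)."""

    bins: tuple[tuple[tuple[int, int], int, int], ...] = field(
        default_factory=lambda: tuple(
            (rng, boys, girls)
            for rng, (boys, girls) in zip(DESIGN_BINS, DEFAULT_DESIGN_COUNTS)
        )
    )

    def __post_init__(self) -> None:
        ranges = sorted(rng for rng, _, _ in self.bins)
        for (lo, hi), (b, g) in ((rng, (b, g)) for rng, b, g in self.bins):
            if lo > hi:
                raise ValueError(f"bin range ({lo}, {hi}) inverted")
            if b < 0 or g < 0:
                raise ValueError("negative counts in design")
        for (_, hi_prev), (lo_next, _) in zip(ranges, ranges[1:]):
            if lo_next <= hi_prev:
                raise ValueError("design bins overlap")

    @property
    def n_boys(self) -> int:
        return sum(b for _, b, _ in self.bins)

    @property
    def n_girls(self) -> int:
        return sum(g for _, _, g in self.bins)

    @property
    def n_total(self) -> int:
        return self.n_boys + self.n_girls

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age_lo": lo, "age_hi": hi, "boys": b, "girls": g, "all": b + g}
            for (lo, hi), b, g in self.bins
        ]
        return pd.DataFrame(rows)


def tabulate_design(cohort: Cohort, bins: Sequence[tuple[int, int]] | None = None
                    ) -> AgeGenderDesign:
    """Cross-tabulate a cohort into the study's age-by-gender design bins.

    Children are counted into the first bin whose closed month range contains
    their age; ages outside every bin raise.
    """
    bins = list(bins) if bins is not None else list(DESIGN_BINS)
    counts = {rng: [0, 0] for rng in bins}
    for rec in cohort:
        for lo, hi in bins:
            if lo <= rec.age_months <= hi:
                counts[(lo, hi)][0 if rec.gender == "M" else 1] += 1
                break
        else:
            raise ValueError(
                f"age {rec.age_months} of {rec.child_id!r} outside all design bins"
            )
    return AgeGenderDesign(
        bins=tuple((rng, counts[rng][0], counts[rng][1]) for rng in bins)
    )


DEFAULT_DIALECT: dict[str, str] = {c: c for c in CSV_COLUMNS}


def read_cohort(path: str | Path, dialect: Mapping[str, str] | None = None,
                label: str | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    ``dialect`` maps canonical column names to the names used in the file;
    omitted entries default to the canonical name.  Rows violating a hard
    invariant are rejected with a row-indexed diagnostic.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    frame = pd.read_csv(path, dtype={colmap["child_id"]: str})
    missing = [v for v in colmap.values() if v not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing column(s) {missing}")
    frame = frame.rename(columns={v: k for k, v in colmap.items()})

    records: list[ChildRecord] = []
    errors: list[str] = []
    int_cols = [c for c in CSV_COLUMNS if c not in ("child_id", "gender")]
    for i, row in frame.iterrows():
        kwargs = {"child_id": str(row["child_id"]), "gender": str(row["gender"])}
        bad_field = None
        for c in int_cols:
            try:
                kwargs[c] = int(row[c])
            except (TypeError, ValueError):
                bad_field = c
                errors.append(f"row {i}: unparseable {c}={row[c]!r}")
                break
        if bad_field:
            continue
        rec = ChildRecord(**kwargs)
        problems = validate_record(rec)
        if problems:
            errors.append(f"row {i} ({rec.child_id!r}): " + "; ".join(problems))
        else:
            records.append(rec)
    if errors:
        raise CohortValidationError(f"{path}:\n" + "\n".join(errors))
    return Cohort(records=records, label=label or path.stem, provenance="empirical")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as CSV with the canonical header; re-readable by
    :func:`read_cohort`."""
    cohort.validate()
    cohort.to_frame().to_csv(Path(path), index=False)
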