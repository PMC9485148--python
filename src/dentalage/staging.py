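"""Data model and I/O for staged-tooth cohorts.

A cohort is a list of subjects, each carrying a chronological age (CA, in
decimal years), a sex, and a Demirjian mineralization stage (A–H) for each
of the seven left-mandibular permanent teeth (FDI 31–37).  This module owns
validation, CSV round-tripping, one-year age binning, and seeded train/test
splitting; everything downstream (score models, refitting, learners,
reports) consumes these types.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: inclusive lower / exclusive upper bound on chronological age (years)
AGE_MIN = 2.0
AGE_MAX = 18.0

#: exclusion rule: a record with more than this many unscorable teeth is invalid
MAX_MISSING_TEETH = 3

CSV_COLUMNS = ["id", "sex", "age", "t31", "t32", "t33", "t34", "t35", "t36", "t37"]


class Tooth(enum.IntEnum):
    """The seven left-mandibular permanent teeth in FDI notation.

    Ordering (31 → 37, central incisor → second molar) is fixed and matches
    the row order of the score tables.
    """

    CENTRAL_INCISOR = 31
    LATERAL_INCISOR = 32
    CANINE = 33
    FIRST_BICUSPID = 34
    SECOND_BICUSPID = 35
    FIRST_MOLAR = 36
    SECOND_MOLAR = 37

    @property
    def label(self) -> str:
        return _TOOTH_LABELS[self]


_TOOTH_LABELS = {
    Tooth.CENTRAL_INCISOR: "Central incisor",
    Tooth.LATERAL_INCISOR: "Lateral incisor",
    Tooth.CANINE: "Canine",
    Tooth.FIRST_BICUSPID: "First bicuspid",
    Tooth.SECOND_BICUSPID: "Second bicuspid",
    Tooth.FIRST_MOLAR: "First molar",
    Tooth.SECOND_MOLAR: "Second molar",
}

TEETH: tuple[Tooth, ...] = tuple(Tooth)


class Stage(enum.IntEnum):
    """Ordinal Demirjian mineralization stage.

    A < B < ... < H; ``MISSING`` marks a tooth that could not be scored
    (absent or unreadable) and sorts below A.
    """

    MISSING = 0
    A = 1
    B = 2
    C = 3
    D = 4
    E = 5
    F = 6
    G = 7
    H = 8

    @classmethod
    def from_letter(cls, letter: str) -> "Stage":
        s = letter.strip().upper()
        if s == "":
            return cls.MISSING
        if s in "ABCDEFGH" and len(s) == 1:
            return cls[s]
        raise StagingError(f"malformed stage letter {letter!r} (expected A-H or empty)")

    @property
    def letter(self) -> str:
        return "" if self is Stage.MISSING else self.name


SCOREABLE_STAGES: tuple[Stage, ...] = tuple(s for s in Stage if s is not Stage.MISSING)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"

    @classmethod
    def parse(cls, text: str) -> "Sex":
        t = text.strip().lower()
        for sex in cls:
            if t == sex.value or t == sex.value[0]:
                return sex
        raise StagingError(f"unrecognized sex {text!r} (expected 'female' or 'male')")


class StagingError(ValueError):
    """Raised on malformed or invariant-violating staging data."""


@dataclass(frozen=True)
class StagingRecord:
    """One subject: id, sex, chronological age, and seven tooth stages."""

    subject_id: str
    sex: Sex
    chronological_age: float
    stages: dict[Tooth, Stage]

    def validate(self) -> None:
        if not (AGE_MIN <= self.chronological_age < AGE_MAX):
            raise StagingError(
                f"record {self.subject_id!r}: chronological age "
                f"{self.chronological_age} outside [{AGE_MIN}, {AGE_MAX})"
            )
        if set(self.stages) != set(TEETH):
            missing = sorted(set(TEETH) - set(self.stages))
            raise StagingError(
                f"record {self.subject_id!r}: stages must cover all 7 teeth "
                f"(missing {[t.name for t in missing]})"
            )
        n_missing = self.n_missing
        if n_missing > MAX_MISSING_TEETH:
            raise StagingError(
                f"record {self.subject_id!r}: {n_missing} unscorable teeth "
                f"(more than {MAX_MISSING_TEETH} excluded)"
            )

    @property
    def n_missing(self) -> int:
        return sum(1 for s in self.stages.values() if s is Stage.MISSING)


@dataclass
class Cohort:
    """Ordered collection of staging records with unique subject ids."""

    records: list[StagingRecord]
    label: str = ""

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise StagingError(f"duplicate subject ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter_sex(self, sex: Sex) -> "Cohort":
        return Cohort(
            [r for r in self.records if r.sex is sex],
            label=f"{self.label}[{sex.value}]",
        )

    def ages(self) -> np.ndarray:
        return np.array([r.chronological_age for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the external CSV column layout."""
        rows = []
        for r in self.records:
            row = {
                "id": r.subject_id,
                "sex": r.sex.value,
                "age": r.chronological_age,
            }
            for tooth in TEETH:
                row[f"t{tooth.value}"] = r.stages[tooth].letter
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


@dataclass(frozen=True)
class AgeBin:
    """Half-open one-year age interval [lower, upper)."""

    lower: float
    upper: float

    def __contains__(self, age: float) -> bool:
        return self.lower <= age < self.upper

    @property
    def label(self) -> str:
        return f"{self.lower:.2f}-{self.upper - 0.01:.2f}"


def standard_bins() -> list[AgeBin]:
    """The sixteen one-year bins covering [2, 18)."""
    return [AgeBin(float(lo), float(lo + 1)) for lo in range(2, 18)]


def read_staging_csv(path, strict: bool = True) -> Cohort:
    """Read a staging CSV (columns id,sex,age,t31..t37) into a validated Cohort.

    Empty stage cells become MISSING.  In strict mode any invariant violation
    raises :class:`StagingError`; in lenient mode offending records are
    dropped and logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise StagingError(f"staging CSV missing columns {missing_cols}")
    records: list[StagingRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            try:
                age = float(row["age"])
            except ValueError as exc:
                raise StagingError(f"row {rownum}: unparseable age {row['age']!r}") from exc
            stages = {}
            for tooth in TEETH:
                try:
                    stages[tooth] = Stage.from_letter(row[f"t{tooth.value}"])
                except StagingError as exc:
                    raise StagingError(f"row {rownum}: {exc}") from exc
            rec = StagingRecord(
                subject_id=row["id"],
                sex=Sex.parse(row["sex"]),
                chronological_age=age,
                stages=stages,
            )
            rec.validate()
        except StagingError:
            if strict:
                raise
            logger.warning("dropping invalid record at CSV row %d", rownum)
            continue
        records.append(rec)
    return Cohort(records, label=str(path))


def write_staging_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the external CSV layout (round-trips with read)."""
    cohort.to_frame().to_csv(path, index=False)


def bin_by_age(cohort: Cohort, bins: list[AgeBin] | None = None) -> dict[AgeBin, Cohort]:
    """Partition a cohort into age bins (each CA falls in exactly one bin)."""
    if bins is None:
        bins = standard_bins()
    out: dict[AgeBin, Cohort] = {}
    for b in bins:
        members = [r for r in cohort.records if r.chronological_age in b]
        out[b] = Cohort(members, label=f"{cohort.label}[{b.label}]")
    assigned = sum(len(c) for c in out.values())
    if assigned != len(cohort):
        raise StagingError(
            f"{len(cohort) - assigned} records fall outside the provided bins"
        )
    return out


def age_distribution_table(cohort: Cohort) -> pd.DataFrame:
    """Sample-distribution summary: per age group, counts by sex plus totals."""
    binned = bin_by_age(cohort)
    rows = []
    for b, sub in binned.items():
        f = sum(1 for r in sub if r.sex is Sex.FEMALE)
        m = sum(1 for r in sub if r.sex is Sex.MALE)
        rows.append({"age_group": b.label, "female": f, "male": m, "both": f + m})
    totals = {
        "age_group": "Total",
        "female": sum(r["female"] for r in rows),
        "male": sum(r["male"] for r in rows),
        "both": sum(r["both"] for r in rows),
    }
    return pd.DataFrame(rows + [totals])


def split_train_test(
    cohort: Cohort, ratio: float = 0.75, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Random disjoint train/test partition with train size = round(n*ratio).

    Rounding is half-up; the permutation is a deterministic function of the
    seed, so identical (cohort, ratio, seed) reproduce the identical split.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    if len(cohort) == 0:
        raise StagingError("cannot split an empty cohort")
    n = len(cohort)
    n_train = int(np.floor(n * ratio + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    train = Cohort([cohort.records[i] for i in train_idx], label=f"{cohort.label}[train]")
    test = Cohort([cohort.records[i] for i in test_idx], label=f"{cohort.label}[test]")
    return train, test
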