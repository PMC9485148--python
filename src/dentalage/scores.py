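"""Score-table dental age estimators.

Two families of score tables exist in the staging literature:

* ``age_sum`` tables (Willems-style): each (tooth, stage) cell is a score in
  years and the seven per-tooth scores sum directly to the dental age.
* ``maturity`` tables (Demirjian-style): cells are maturity points; the
  summed maturity score is converted to an age through a sex-specific
  piecewise-linear conversion curve.

The modified southern-China ``age_sum`` tables ship with the package as JSON
fixtures (:func:`builtin_modified_tables`); published Willems-1993 or
Demirjian-1973 tables are supplied by the user as data files in the same
format.  Cells printed as "–" in the source tables are ABSENT: looking them
up is an error, mirroring stages never observed in the reference cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .staging import SCOREABLE_STAGES, TEETH, Sex, Stage, StagingRecord, Tooth


class ScoreTableError(ValueError):
    """Raised on malformed score tables or invalid lookups."""


class AbsentCellError(ScoreTableError):
    """Lookup hit a cell the table does not define (a "–" cell)."""

    def __init__(self, tooth: Tooth, stage: Stage, name: str = ""):
        self.tooth = tooth
        self.stage = stage
        super().__init__(
            f"score table {name!r} has no score for tooth {tooth.value} "
            f"({tooth.label}) at stage {stage.letter}"
        )


@dataclass(frozen=True)
class ScoreTable:
    """Sex-specific mapping (tooth, stage) -> score.

    ``scores`` uses None for ABSENT cells; defined scores are finite floats.
    """

    name: str
    sex: Sex
    kind: str  # "age_sum" | "maturity"
    scores: dict[Tooth, dict[Stage, float | None]]

    def __post_init__(self):
        if self.kind not in ("age_sum", "maturity"):
            raise ScoreTableError(f"unknown table kind {self.kind!r}")
        for tooth in TEETH:
            if tooth not in self.scores:
                raise ScoreTableError(f"table {self.name!r} missing tooth {tooth.value}")
            row = self.scores[tooth]
            for stage in SCOREABLE_STAGES:
                if stage not in row:
                    raise ScoreTableError(
                        f"table {self.name!r} tooth {tooth.value} missing stage {stage.letter}"
                    )
                v = row[stage]
                if v is not None and not math.isfinite(v):
                    raise ScoreTableError(
                        f"table {self.name!r} tooth {tooth.value} stage "
                        f"{stage.letter}: non-finite score {v}"
                    )

    def lookup(self, tooth: Tooth, stage: Stage) -> float:
        if stage is Stage.MISSING:
            raise ScoreTableError("cannot look up a MISSING stage")
        v = self.scores[tooth][stage]
        if v is None:
            raise AbsentCellError(tooth, stage, self.name)
        return float(v)

    def has_cell(self, tooth: Tooth, stage: Stage) -> bool:
        return stage is not Stage.MISSING and self.scores[tooth][stage] is not None

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return (
            self.name == other.name
            and self.sex == other.sex
            and self.kind == other.kind
            and all(
                self.scores[t][s] == other.scores[t][s]
                for t in TEETH
                for s in SCOREABLE_STAGES
            )
        )


def lookup_score(table: ScoreTable, tooth: Tooth, stage: Stage) -> float:
    """Return the table cell for (tooth, stage); errors on ABSENT or MISSING."""
    return table.lookup(tooth, stage)


@dataclass(frozen=True)
class MaturityConversion:
    """Piecewise-linear maturity-score -> age conversion curve for one sex."""

    sex: Sex
    knots: tuple[tuple[float, float], ...]  # (maturity score, age years)

    def __post_init__(self):
        if len(self.knots) == 0:
            raise ScoreTableError("maturity conversion needs at least one knot")
        scores = [k[0] for k in self.knots]
        ages = [k[1] for k in self.knots]
        if any(b <= a for a, b in zip(scores, scores[1:])):
            raise ScoreTableError("conversion maturity scores must be strictly increasing")
        if any(b < a for a, b in zip(ages, ages[1:])):
            raise ScoreTableError("conversion ages must be nondecreasing")

    def age_at(self, maturity: float) -> tuple[float, bool]:
        """Interpolated age and a flag set when maturity fell outside the knots."""
        scores = np.array([k[0] for k in self.knots])
        ages = np.array([k[1] for k in self.knots])
        clamped = maturity < scores[0] or maturity > scores[-1]
        return float(np.interp(maturity, scores, ages)), bool(clamped)


@dataclass(frozen=True)
class DentalAgeEstimate:
    """A single subject's estimated dental age (DA, years)."""

    subject_id: str
    dental_age: float
    method: str
    partial: bool = False  # some teeth skipped under the "skip" missing policy
    clamped: bool = False  # maturity fell outside the conversion range


def estimate_age_sum(
    record: StagingRecord, table: ScoreTable, missing_policy: str = "error"
) -> DentalAgeEstimate:
    """Dental age as the direct sum of the seven per-tooth stage scores.

    ``missing_policy``: "error" (default) rejects records with unscorable
    teeth; "skip" sums the scorable teeth only and flags the estimate as
    partial.
    """
    if table.kind != "age_sum":
        raise ScoreTableError(f"table {table.name!r} is not an age_sum table")
    if table.sex is not record.sex:
        raise ScoreTableError(
            f"table sex {table.sex.value} does not match record sex {record.sex.value}"
        )
    if missing_policy not in ("error", "skip"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    total = 0.0
    skipped = 0
    for tooth in TEETH:
        stage = record.stages[tooth]
        if stage is Stage.MISSING:
            if missing_policy == "error":
                raise ScoreTableError(
                    f"record {record.subject_id!r}: tooth {tooth.value} is "
                    "unscorable and missing_policy is 'error'"
                )
            skipped += 1
            continue
        total += table.lookup(tooth, stage)
    return DentalAgeEstimate(
        subject_id=record.subject_id,
        dental_age=total,
        method=table.name,
        partial=skipped > 0,
    )


def estimate_age_maturity(
    record: StagingRecord,
    table: ScoreTable,
    conv: MaturityConversion,
    missing_policy: str = "error",
) -> DentalAgeEstimate:
    """Dental age via summed maturity score and a conversion curve."""
    if table.kind != "maturity":
        raise ScoreTableError(f"table {table.name!r} is not a maturity table")
    if table.sex is not record.sex or conv.sex is not record.sex:
        raise ScoreTableError("table/conversion sex must match the record sex")
    if missing_policy not in ("error", "skip"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    maturity = 0.0
    skipped = 0
    for tooth in TEETH:
        stage = record.stages[tooth]
        if stage is Stage.MISSING:
            if missing_policy == "error":
                raise ScoreTableError(
                    f"record {record.subject_id!r}: tooth {tooth.value} is "
                    "unscorable and missing_policy is 'error'"
                )
            skipped += 1
            continue
        maturity += table.lookup(tooth, stage)
    age, clamped = conv.age_at(maturity)
    return DentalAgeEstimate(
        subject_id=record.subject_id,
        dental_age=age,
        method=table.name,
        partial=skipped > 0,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def table_to_dict(table: ScoreTable) -> dict:
    return {
        "name": table.name,
        "sex": table.sex.value,
        "kind": table.kind,
        "scores": {
            str(t.value): {s.letter: table.scores[t][s] for s in SCOREABLE_STAGES}
            for t in TEETH
        },
    }


def table_from_dict(obj: dict) -> ScoreTable:
    for key in ("name", "sex", "kind", "scores"):
        if key not in obj:
            raise ScoreTableError(f"score table JSON missing field {key!r}")
    raw = obj["scores"]
    scores: dict[Tooth, dict[Stage, float | None]] = {}
    for tooth in TEETH:
        key = str(tooth.value)
        if key not in raw:
            raise ScoreTableError(f"score table JSON missing tooth {key}")
        row = {}
        for stage in SCOREABLE_STAGES:
            if stage.letter not in raw[key]:
                raise ScoreTableError(
                    f"score table JSON tooth {key} missing stage {stage.letter}"
                )
            v = raw[key][stage.letter]
            if v is not None:
                v = float(v)
                if not math.isfinite(v):
                    raise ScoreTableError(
                        f"score table JSON tooth {key} stage {stage.letter}: "
                        f"non-finite score"
                    )
            row[stage] = v
        scores[tooth] = row
    return ScoreTable(
        name=str(obj["name"]), sex=Sex.parse(obj["sex"]), kind=str(obj["kind"]), scores=scores
    )


def save_score_table(table: ScoreTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(table_to_dict(table), fh, indent=2, allow_nan=False)
        fh.write("\n")


def load_score_table(path) -> ScoreTable:
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh, parse_constant=_reject_constant)
        except json.JSONDecodeError as exc:
            raise ScoreTableError(f"invalid score table JSON: {exc}") from exc
    return table_from_dict(obj)


def _reject_constant(name):
    raise ScoreTableError(f"non-finite constant {name!r} in score table JSON")


def load_conversion(path) -> MaturityConversion:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if "sex" not in obj or "knots" not in obj:
        raise ScoreTableError("conversion JSON needs 'sex' and 'knots'")
    knots = tuple((float(s), float(a)) for s, a in obj["knots"])
    return MaturityConversion(sex=Sex.parse(obj["sex"]), knots=knots)


def save_conversion(conv: MaturityConversion, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"sex": conv.sex.value, "knots": [list(k) for k in conv.knots]},
            fh,
            indent=2,
        )
        fh.write("\n")


def builtin_modified_tables() -> tuple[ScoreTable, ScoreTable]:
    """The modified southern-China age-sum score tables (female, male)."""
    out = []
    for fname in ("modified_table_female.json", "modified_table_male.json"):
        text = resources.files("dentalage.data").joinpath(fname).read_text()
        out.append(table_from_dict(json.loads(text)))
    return out[0], out[1]
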