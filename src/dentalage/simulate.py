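"""Synthetic staged-tooth cohort generator with known ground truth.

No public staging dataset accompanies the reference population, so testing
the estimators, the refit procedure, and the learners requires a cohort
whose generating mechanism is known.  The model here is a threshold
process on a latent developmental clock:

* each tooth has a sex-specific row of stage-attainment ages
  τ_A … τ_H — the mean age at which the tooth first reaches each stage —
  with increasing gaps (development is fast early and slows toward apex
  closure);
* each subject carries one shared tempo offset δ ~ N(0, σ) (children run
  uniformly early or late across their whole dentition), and each tooth an
  independent jitter ε ~ N(0, jitter_sd);
* the attained stage is the highest stage s with τ_s ≤ age + δ + ε.  Stages
  whose τ is undefined were reached before the cohort's lower age bound and
  act as a floor: the subject is at least at the highest undefined stage.

The shared offset makes teeth correlated within a subject, the thresholds
make stage-vs-age monotone, and the widening gaps make the stage-to-age
relation nonlinear — the three features the downstream analyses exploit.

Default parameters live in ``data/maturation_defaults.json`` (versioned);
the default cohort layout reproduces the reference study's sample
distribution (n = 1477: 833 female, 644 male, sixteen one-year bins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .scores import ScoreTable, estimate_age_sum
from .staging import (
    SCOREABLE_STAGES,
    TEETH,
    AgeBin,
    Cohort,
    Sex,
    Stage,
    StagingRecord,
    Tooth,
)

#: per (sex, one-year bin lower edge) subject counts of the reference cohort
TABLE1_COUNTS: dict[Sex, dict[int, int]] = {
    Sex.FEMALE: {
        2: 5, 3: 19, 4: 33, 5: 49, 6: 59, 7: 53, 8: 41, 9: 37,
        10: 37, 11: 64, 12: 123, 13: 111, 14: 60, 15: 69, 16: 36, 17: 37,
    },
    Sex.MALE: {
        2: 1, 3: 11, 4: 39, 5: 45, 6: 52, 7: 43, 8: 38, 9: 34,
        10: 38, 11: 51, 12: 94, 13: 73, 14: 40, 15: 42, 16: 28, 17: 15,
    },
}


@dataclass(frozen=True)
class MaturationParams:
    """Sex- and tooth-specific stage-attainment ages plus noise scales.

    ``attainment[sex][tooth][stage]`` is τ in years, or None when the stage
    is reached before the cohort window opens (the floor stages).
    ``offset_sd`` is the between-subject tempo spread σ; ``tooth_jitter_sd``
    the within-subject per-tooth noise.  Both in years.
    """

    attainment: dict[Sex, dict[Tooth, dict[Stage, float | None]]]
    offset_sd: float
    tooth_jitter_sd: float
    version: int = 1

    def __post_init__(self):
        if self.offset_sd < 0 or self.tooth_jitter_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        for sex, teeth in self.attainment.items():
            for tooth, row in teeth.items():
                taus = [row[s] for s in SCOREABLE_STAGES if row.get(s) is not None]
                if any(b <= a for a, b in zip(taus, taus[1:])):
                    raise ValueError(
                        f"attainment ages for {sex.value} tooth {tooth.value} "
                        "must be strictly increasing"
                    )

    def floor_stage(self, sex: Sex, tooth: Tooth) -> Stage:
        """Highest stage with undefined τ: everyone is at least this stage."""
        row = self.attainment[sex][tooth]
        floor = Stage.A
        for s in SCOREABLE_STAGES:
            if row.get(s) is None:
                floor = s
            else:
                break
        return floor

    def stage_at(self, sex: Sex, tooth: Tooth, effective_age: float) -> Stage:
        """Attained stage for a latent clock reading (age + δ + ε)."""
        row = self.attainment[sex][tooth]
        stage = self.floor_stage(sex, tooth)
        for s in SCOREABLE_STAGES:
            tau = row.get(s)
            if tau is not None and tau <= effective_age:
                stage = s
        return stage


def default_maturation_params() -> MaturationParams:
    """The versioned default parameter set shipped with the package."""
    text = resources.files("dentalage.data").joinpath("maturation_defaults.json").read_text()
    obj = json.loads(text)
    attainment: dict[Sex, dict[Tooth, dict[Stage, float | None]]] = {}
    for sex_name, teeth in obj["attainment"].items():
        sex = Sex.parse(sex_name)
        attainment[sex] = {}
        for tooth_key, row in teeth.items():
            tooth = Tooth(int(tooth_key))
            attainment[sex][tooth] = {
                Stage[letter]: (None if v is None else float(v)) for letter, v in row.items()
            }
    return MaturationParams(
        attainment=attainment,
        offset_sd=float(obj["offset_sd"]),
        tooth_jitter_sd=float(obj["tooth_jitter_sd"]),
        version=int(obj["version"]),
    )


@dataclass(frozen=True)
class CohortSpec:
    """How many subjects to draw per (sex, one-year age bin), plus the seed.

    Ages are sampled uniformly within each bin.  The default layout is the
    reference study's sample distribution.
    """

    counts: dict[Sex, dict[int, int]] = field(
        default_factory=lambda: {s: dict(c) for s, c in TABLE1_COUNTS.items()}
    )
    seed: int = 0

    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def __post_init__(self):
        if self.total() <= 0:
            raise ValueError("cohort spec must request at least one subject")
        for per_bin in self.counts.values():
            if any(n < 0 for n in per_bin.values()):
                raise ValueError("bin counts must be nonnegative")


def scaled_spec(total: int, seed: int = 0) -> CohortSpec:
    """Cohort spec with the reference age/sex profile scaled to ``total``.

    Counts are scaled proportionally and rounded; remainders go to the
    largest bins so the requested total is met exactly.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    ref_total = sum(sum(c.values()) for c in TABLE1_COUNTS.values())
    counts: dict[Sex, dict[int, int]] = {}
    cells = [
        (sex, lo, n) for sex, per_bin in TABLE1_COUNTS.items() for lo, n in per_bin.items()
    ]
    scaled = [(sex, lo, n * total / ref_total) for sex, lo, n in cells]
    floors = [(sex, lo, int(np.floor(x))) for sex, lo, x in scaled]
    short = total - sum(f for _, _, f in floors)
    # hand out the remainder by largest fractional part, stable order
    order = sorted(
        range(len(scaled)),
        key=lambda i: (-(scaled[i][2] - floors[i][2]), i),
    )
    bonus = set(order[:short])
    for i, (sex, lo, f) in enumerate(floors):
        counts.setdefault(sex, {})[lo] = f + (1 if i in bonus else 0)
    return CohortSpec(counts=counts, seed=seed)


@dataclass
class GroundTruth:
    """Latent variables behind a generated cohort (per subject, in order)."""

    offsets: dict[str, float]
    jitters: dict[str, dict[Tooth, float]]
    params: MaturationParams
    seed: int


def generate_cohort(
    spec: CohortSpec | None = None, params: MaturationParams | None = None
) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the threshold model; deterministic given the seed."""
    spec = spec or CohortSpec()
    params = params or default_maturation_params()
    rng = np.random.default_rng(spec.seed)
    records: list[StagingRecord] = []
    offsets: dict[str, float] = {}
    jitters: dict[str, dict[Tooth, float]] = {}
    i = 0
    for sex in (Sex.FEMALE, Sex.MALE):
        for lo in sorted(spec.counts.get(sex, {})):
            for _ in range(spec.counts[sex][lo]):
                i += 1
                sid = f"S{i:05d}"
                age = float(rng.uniform(lo, lo + 1))
                delta = float(rng.normal(0.0, params.offset_sd))
                stages: dict[Tooth, Stage] = {}
                eps: dict[Tooth, float] = {}
                for tooth in TEETH:
                    e = float(rng.normal(0.0, params.tooth_jitter_sd))
                    eps[tooth] = e
                    stages[tooth] = params.stage_at(sex, tooth, age + delta + e)
                rec = StagingRecord(sid, sex, age, stages)
                rec.validate()
                records.append(rec)
                offsets[sid] = delta
                jitters[sid] = eps
    cohort = Cohort(records, label=f"synthetic(seed={spec.seed})")
    return cohort, GroundTruth(offsets, jitters, params, spec.seed)


def generate_from_score_table(
    table: ScoreTable,
    spec: CohortSpec | None = None,
    noise_sd: float = 0.0,
    params: MaturationParams | None = None,
    on_absent: str = "resample",
) -> Cohort:
    """Cohort whose CA exactly satisfies the additive score model.

    Stages are drawn as in :func:`generate_cohort`, then the chronological
    age is REPLACED by the table's score sum plus N(0, noise_sd) noise
    (clipped into the valid age window), so an age-sum estimator with the
    generating table recovers CA up to that noise.  Used for refit recovery
    tests.  ``on_absent``: "resample" redraws a subject whose stages hit an
    undefined table cell; "error" raises.
    """
    if table.kind != "age_sum":
        raise ValueError("generate_from_score_table needs an age_sum table")
    if on_absent not in ("resample", "error"):
        raise ValueError(f"unknown on_absent policy {on_absent!r}")
    spec = spec or CohortSpec()
    params = params or default_maturation_params()
    sex = table.sex
    rng = np.random.default_rng(spec.seed)
    records: list[StagingRecord] = []
    i = 0
    for lo in sorted(spec.counts.get(sex, {})):
        for _ in range(spec.counts[sex][lo]):
            i += 1
            sid = f"S{i:05d}"
            for _attempt in range(1000):
                age = float(rng.uniform(lo, lo + 1))
                delta = float(rng.normal(0.0, params.offset_sd))
                stages = {
                    tooth: params.stage_at(
                        sex, tooth, age + delta + float(rng.normal(0.0, params.tooth_jitter_sd))
                    )
                    for tooth in TEETH
                }
                if all(table.has_cell(t, s) for t, s in stages.items()):
                    break
                if on_absent == "error":
                    raise ValueError(
                        f"generated stages hit an undefined cell of table {table.name!r}"
                    )
            else:
                raise ValueError(
                    f"could not draw stages covered by table {table.name!r} in bin {lo}"
                )
            score_sum = sum(table.lookup(t, s) for t, s in stages.items())
            ca = score_sum + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
            ca = float(np.clip(ca, 2.0, 17.99))
            rec = StagingRecord(sid, sex, ca, stages)
            rec.validate()
            records.append(rec)
    return Cohort(records, label=f"table-generated(seed={spec.seed})")
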