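"""Reweighting a score table by non-intercept least squares.

Given a sex-specific cohort and a base age-sum score table, chronological
age is regressed on stage-score predictors with NO intercept, and the
fitted coefficients are folded back into the table, producing a modified
score table adapted to the cohort's population.

Two design-matrix strategies are supported:

* ``per_tooth`` — 7 columns, one per tooth, holding the base-table score of
  the stage that tooth attained; the fit yields one scale factor per tooth.
  This reweighting of each tooth's parameters is the classical procedure
  (and the pipeline default).  Note that a per-tooth scale can flip or
  preserve the sign pattern of a base row — published age-sum tables carry
  negative scores for early stages of some teeth.
* ``per_cell`` — one 0/1 indicator column per (tooth, stage) cell observed
  in the cohort; the fitted coefficient IS the modified cell score.  The
  most flexible additive model; used for exact-recovery validation.

Cells never observed in the fitting cohort stay ABSENT in the output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scores import ScoreTable
from .staging import SCOREABLE_STAGES, TEETH, Cohort, Sex, Stage, Tooth

STRATEGIES = ("per_tooth", "per_cell")


class RefitError(ValueError):
    pass


class SingularDesignError(RefitError):
    """The design matrix is rank deficient."""

    def __init__(self, labels):
        self.dependent_labels = list(labels)
        super().__init__(
            f"design matrix is rank deficient; linearly dependent columns "
            f"involve {self.dependent_labels}"
        )


@dataclass(frozen=True)
class RefitConfig:
    strategy: str
    sex: Sex

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise RefitError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")


@dataclass
class DesignMatrix:
    """No-intercept design: X (n x p), response y = chronological ages.

    ``labels`` name the columns: a Tooth under per_tooth, a (Tooth, Stage)
    pair under per_cell.  ``n_excluded`` counts records dropped for
    unscorable teeth.
    """

    X: np.ndarray
    y: np.ndarray
    labels: list
    strategy: str
    n_excluded: int = 0


@dataclass
class RefitResult:
    coefficients: dict
    modified_table: ScoreTable
    residual_sd: float
    n: int
    strategy: str


def build_design_matrix(cohort: Cohort, base: ScoreTable, config: RefitConfig) -> DesignMatrix:
    """Assemble the no-intercept design for one sex-specific cohort.

    Records with any MISSING stage are excluded (and counted); under
    per_tooth an ABSENT base cell for an observed stage is an error, since
    that tooth's predictor would be undefined.
    """
    for rec in cohort:
        if rec.sex is not config.sex:
            raise RefitError(
                f"record {rec.subject_id!r} sex {rec.sex.value} does not match "
                f"config sex {config.sex.value}"
            )
    usable = []
    n_excluded = 0
    for rec in cohort:
        if rec.n_missing > 0:
            n_excluded += 1
            continue
        usable.append(rec)
    if not usable:
        raise RefitError("no usable records (all have unscorable teeth or cohort empty)")

    y = np.array([r.chronological_age for r in usable], dtype=float)

    if config.strategy == "per_tooth":
        X = np.empty((len(usable), len(TEETH)))
        for i, rec in enumerate(usable):
            for j, tooth in enumerate(TEETH):
                X[i, j] = base.lookup(tooth, rec.stages[tooth])  # AbsentCellError propagates
        labels = list(TEETH)
    else:  # per_cell
        observed: list[tuple[Tooth, Stage]] = []
        seen = set()
        for rec in usable:
            for tooth in TEETH:
                key = (tooth, rec.stages[tooth])
                if key not in seen:
                    seen.add(key)
                    observed.append(key)
        observed.sort(key=lambda k: (k[0].value, k[1].value))
        col = {key: j for j, key in enumerate(observed)}
        X = np.zeros((len(usable), len(observed)))
        for i, rec in enumerate(usable):
            for tooth in TEETH:
                X[i, col[(tooth, rec.stages[tooth])]] = 1.0
        labels = observed

    return DesignMatrix(X=X, y=y, labels=labels, strategy=config.strategy, n_excluded=n_excluded)


def fit_nonintercept_ols(design: DesignMatrix, anchor: np.ndarray | None = None) -> dict:
    """Least squares through the origin: b = argmin ||y - Xb||^2.

    With a full-rank design the solution is unique.  A per-cell indicator
    design is structurally rank deficient — each tooth's indicators sum to
    the all-ones vector, so cell scores are identified only up to
    between-tooth shifts that cancel in every complete record's sum.  In
    that case ``anchor`` selects, among the least-squares solutions (all of
    which fit and predict complete records identically), the one closest to
    the anchor vector: b = anchor + lstsq(X, y − X·anchor).  Without an
    anchor a rank-deficient design raises :class:`SingularDesignError`
    naming columns involved in the dependency.
    """
    X, y = design.X, design.y
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] and anchor is None:
        # identify columns whose removal does not lower the rank
        dependent = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                dependent.append(design.labels[j])
        raise SingularDesignError(dependent or design.labels)
    if anchor is None:
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
    else:
        anchor = np.asarray(anchor, dtype=float)
        if anchor.shape != (X.shape[1],):
            raise RefitError("anchor length must match the number of design columns")
        correction, *_ = np.linalg.lstsq(X, y - X @ anchor, rcond=None)
        b = anchor + correction
    return {label: float(coef) for label, coef in zip(design.labels, b)}


def derive_modified_table(coeffs: dict, base: ScoreTable, config: RefitConfig) -> ScoreTable:
    """Fold fitted coefficients back into an age-sum score table.

    per_tooth: modified(t, s) = b_t * base(t, s) wherever base defines (t, s).
    per_cell:  modified(t, s) = b_(t,s) for observed cells; others ABSENT.
    """
    scores: dict[Tooth, dict[Stage, float | None]] = {
        t: {s: None for s in SCOREABLE_STAGES} for t in TEETH
    }
    if config.strategy == "per_tooth":
        if set(coeffs) != set(TEETH):
            raise RefitError("per_tooth coefficients must be labelled by the 7 teeth")
        for tooth in TEETH:
            for stage in SCOREABLE_STAGES:
                if base.has_cell(tooth, stage):
                    scores[tooth][stage] = coeffs[tooth] * base.lookup(tooth, stage)
    else:
        for label in coeffs:
            if (
                not isinstance(label, tuple)
                or len(label) != 2
                or not isinstance(label[0], Tooth)
                or not isinstance(label[1], Stage)
            ):
                raise RefitError(f"per_cell coefficient label {label!r} is not (Tooth, Stage)")
        for (tooth, stage), b in coeffs.items():
            scores[tooth][stage] = float(b)
    return ScoreTable(
        name=f"refit-{config.strategy}-{config.sex.value}-from-{base.name}",
        sex=config.sex,
        kind="age_sum",
        scores=scores,
    )


def refit(cohort: Cohort, base: ScoreTable, config: RefitConfig) -> RefitResult:
    """Full reweighting pass: design, no-intercept fit, modified table.

    Under per_cell the fit is anchored to the base table: among the
    equivalent least-squares solutions the one with minimal total change to
    the base scores is reported (cells the base leaves undefined anchor at
    zero).  Anchoring never changes fitted values or predictions for
    complete records; it only pins down the printed table.
    """
    design = build_design_matrix(cohort, base, config)
    anchor = None
    if config.strategy == "per_cell":
        anchor = np.array(
            [
                base.lookup(t, s) if base.has_cell(t, s) else 0.0
                for (t, s) in design.labels
            ]
        )
    coeffs = fit_nonintercept_ols(design, anchor=anchor)
    table = derive_modified_table(coeffs, base, config)
    b = np.array([coeffs[label] for label in design.labels])
    resid = design.y - design.X @ b
    n, p = design.X.shape
    dof = max(n - p, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    return RefitResult(
        coefficients=coeffs,
        modified_table=table,
        residual_sd=residual_sd,
        n=n,
        strategy=config.strategy,
    )
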