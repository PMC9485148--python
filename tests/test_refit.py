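import numpy as np
import pytest

from dentalage.refit import (
    DesignMatrix,
    RefitConfig,
    RefitError,
    SingularDesignError,
    build_design_matrix,
    derive_modified_table,
    fit_nonintercept_ols,
    refit,
)
from dentalage.scores import ScoreTable, builtin_modified_tables, estimate_age_sum
from dentalage.simulate import generate_from_score_table, scaled_spec
from dentalage.staging import SCOREABLE_STAGES, TEETH, Cohort, Sex, Stage, Tooth

from conftest import make_record


def scaled_table(base: ScoreTable, factors: dict) -> ScoreTable:
    scores = {
        t: {
            s: (None if not base.has_cell(t, s) else factors[t] * base.lookup(t, s))
            for s in SCOREABLE_STAGES
        }
        for t in TEETH
    }
    return ScoreTable(name="scaled", sex=base.sex, kind="age_sum", scores=scores)


class TestDesignMatrix:
    def test_per_tooth_row_holds_base_scores(self, modified_tables):
        male = modified_tables["male"]
        rec = make_record(stages="HHHHHHH", age=15.0)
        cfg = RefitConfig("per_tooth", Sex.MALE)
        design = build_design_matrix(Cohort([rec]), male, cfg)
        expected = [male.lookup(t, Stage.H) for t in TEETH]
        assert design.X.shape == (1, 7)
        assert np.allclose(design.X[0], expected)

    def test_per_cell_indicator_columns(self, modified_tables):
        male = modified_tables["male"]
        recs = [
            make_record("A", stages="HHHHHHH", age=15.0),
            make_record("B", stages="GHHHHHH", age=14.0),
        ]
        cfg = RefitConfig("per_cell", Sex.MALE)
        design = build_design_matrix(Cohort(recs), male, cfg)
        labels = set(design.labels)
        assert (Tooth.CENTRAL_INCISOR, Stage.H) in labels
        assert (Tooth.CENTRAL_INCISOR, Stage.G) in labels
        assert design.X.sum(axis=1).tolist() == [7.0, 7.0]  # one cell per tooth

    def test_absent_base_cell_propagates(self, modified_tables):
        # stage C canine is a dashed cell of the male table
        rec = make_record(stages="HHCHHHH", age=9.0)
        cfg = RefitConfig("per_tooth", Sex.MALE)
        from dentalage.scores import AbsentCellError

        with pytest.raises(AbsentCellError):
            build_design_matrix(Cohort([rec]), modified_tables["male"], cfg)

    def test_missing_stage_records_excluded_and_counted(self, modified_tables):
        recs = [
            make_record("A", stages="HHHHHHH", age=15.0),
            make_record("B", stages="HHH.HHH", age=14.0),
        ]
        cfg = RefitConfig("per_tooth", Sex.MALE)
        design = build_design_matrix(Cohort(recs), modified_tables["male"], cfg)
        assert design.X.shape[0] == 1
        assert design.n_excluded == 1

    def test_sex_mismatch_rejected(self, modified_tables):
        rec = make_record(sex=Sex.FEMALE)
        with pytest.raises(RefitError, match="sex"):
            build_design_matrix(
                Cohort([rec]), modified_tables["male"], RefitConfig("per_tooth", Sex.MALE)
            )

    def test_unknown_strategy_rejected(self):
        with pytest.raises(RefitError):
            RefitConfig("per_stage", Sex.MALE)


class TestNoInterceptOLS:
    def _design(self, X, y):
        X = np.asarray(X, dtype=float)
        return DesignMatrix(
            X=X, y=np.asarray(y, dtype=float),
            labels=[f"c{i}" for i in range(X.shape[1])], strategy="per_tooth",
        )

    def test_identity_column(self):
        y = np.array([3.0, 5.0, 9.0])
        coeffs = fit_nonintercept_ols(self._design(y[:, None], y))
        assert coeffs["c0"] == pytest.approx(1.0, abs=1e-12)

    def test_doubled_column_halves_coefficient(self):
        y = np.array([3.0, 5.0, 9.0])
        coeffs = fit_nonintercept_ols(self._design(2 * y[:, None], y))
        assert coeffs["c0"] == pytest.approx(0.5, abs=1e-12)

    def test_three_point_closed_form(self):
        # b = sum(x*y)/sum(x^2) = (2 + 8 + 21)/(1 + 4 + 9) = 31/14
        coeffs = fit_nonintercept_ols(self._design([[1], [2], [3]], [2, 4, 7]))
        assert coeffs["c0"] == pytest.approx(31 / 14, abs=1e-12)

    def test_no_intercept_fit_differs_from_centered_fit(self):
        # a nonzero-mean response with a constant predictor column forces
        # the through-origin line away from the ordinary regression line
        X = np.array([[1.0], [1.0], [1.0], [1.0]])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        coeffs = fit_nonintercept_ols(self._design(X, y))
        assert coeffs["c0"] == pytest.approx(4.0)  # mean, not slope 0 + intercept

    def test_rank_deficiency_raises_and_names_columns(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(SingularDesignError) as err:
            fit_nonintercept_ols(self._design(X, [1, 2, 3]))
        assert set(err.value.dependent_labels) == {"c0", "c1"}

    def test_anchored_solution_is_least_squares(self, rng):
        # rank-deficient design: anchored solution must still minimize SSE
        X = np.column_stack([np.ones(20), np.ones(20)])
        y = rng.normal(5.0, 1.0, size=20)
        design = self._design(X, y)
        coeffs = fit_nonintercept_ols(design, anchor=np.array([1.0, 2.0]))
        b = np.array([coeffs["c0"], coeffs["c1"]])
        resid = y - X @ b
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)
        # anchored direction: solution minimizes distance to the anchor
        assert b[1] - b[0] == pytest.approx(1.0, abs=1e-9)


class TestDeriveTable:
    def test_identity_weights_reproduce_base(self, modified_tables):
        male = modified_tables["male"]
        coeffs = {t: 1.0 for t in TEETH}
        out = derive_modified_table(coeffs, male, RefitConfig("per_tooth", Sex.MALE))
        for t in TEETH:
            for s in SCOREABLE_STAGES:
                assert out.scores[t][s] == (
                    male.scores[t][s] if male.has_cell(t, s) else None
                )

    def test_per_tooth_scaling(self, modified_tables):
        male = modified_tables["male"]
        coeffs = {t: 1.0 for t in TEETH}
        coeffs[Tooth.FIRST_BICUSPID] = 2.0
        out = derive_modified_table(coeffs, male, RefitConfig("per_tooth", Sex.MALE))
        assert out.lookup(Tooth.FIRST_BICUSPID, Stage.D) == pytest.approx(2.88)

    def test_per_cell_unobserved_cells_absent(self, modified_tables):
        coeffs = {(Tooth.CENTRAL_INCISOR, Stage.H): 1.2}
        out = derive_modified_table(
            coeffs, modified_tables["male"], RefitConfig("per_cell", Sex.MALE)
        )
        assert out.lookup(Tooth.CENTRAL_INCISOR, Stage.H) == 1.2
        assert not out.has_cell(Tooth.CENTRAL_INCISOR, Stage.G)

    def test_label_mismatch_is_error(self, modified_tables):
        with pytest.raises(RefitError):
            derive_modified_table(
                {"bogus": 1.0}, modified_tables["male"], RefitConfig("per_cell", Sex.MALE)
            )


class TestRefitRecovery:
    def test_per_cell_recovers_generating_table(self, modified_tables):
        female = modified_tables["female"]
        cohort = generate_from_score_table(female, scaled_spec(300, seed=21), noise_sd=0.0)
        result = refit(cohort, female, RefitConfig("per_cell", Sex.FEMALE))
        assert result.residual_sd == pytest.approx(0.0, abs=1e-8)
        for (tooth, stage), b in result.coefficients.items():
            assert b == pytest.approx(female.lookup(tooth, stage), abs=1e-8)

    def test_per_tooth_recovers_scale_factors(self, modified_tables):
        male = modified_tables["male"]
        factors = dict(zip(TEETH, [1.1, 0.9, 1.2, 0.95, 1.05, 1.15, 1.0]))
        generating = scaled_table(male, factors)
        cohort = generate_from_score_table(generating, scaled_spec(300, seed=22), noise_sd=0.0)
        result = refit(cohort, male, RefitConfig("per_tooth", Sex.MALE))
        for tooth in TEETH:
            assert result.coefficients[tooth] == pytest.approx(factors[tooth], abs=1e-8)
        assert result.residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_noisy_cohort_residual_sd_in_band(self, modified_tables):
        male = modified_tables["male"]
        cohort = generate_from_score_table(male, scaled_spec(1000, seed=23), noise_sd=1.0)
        result = refit(cohort, male, RefitConfig("per_tooth", Sex.MALE))
        assert 0.8 <= result.residual_sd <= 1.2

    def test_residual_orthogonality(self, modified_tables, default_cohort):
        for sex, key in ((Sex.FEMALE, "female"), (Sex.MALE, "male")):
            base = modified_tables[key]
            sub = default_cohort.filter_sex(sex)
            for strategy in ("per_tooth", "per_cell"):
                cfg = RefitConfig(strategy, sex)
                design = build_design_matrix(sub, base, cfg)
                anchor = None
                if strategy == "per_cell":
                    anchor = np.zeros(design.X.shape[1])
                coeffs = fit_nonintercept_ols(design, anchor=anchor)
                b = np.array([coeffs[l] for l in design.labels])
                assert np.allclose(design.X.T @ (design.y - design.X @ b), 0.0, atol=1e-8)

    def test_refit_shrinks_bias_of_base_table(self, modified_tables, default_cohort):
        """Reweighting must reduce |mean AD| relative to the base table."""
        from dentalage.metrics import PairedAges

        for sex, key in ((Sex.FEMALE, "female"), (Sex.MALE, "male")):
            base = modified_tables[key]
            sub = default_cohort.filter_sex(sex)
            result = refit(sub, base, RefitConfig("per_tooth", sex))

            def mean_ad(table):
                ads = [
                    estimate_age_sum(r, table).dental_age - r.chronological_age
                    for r in sub
                ]
                return abs(float(np.mean(ads)))

            assert mean_ad(result.modified_table) <= mean_ad(base)
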