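"""Activity-factor schemes and the energy-requirement prediction models."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from opsfuel import reference
from opsfuel.accounting import Participant
from opsfuel.paf import (
    DEFAULT_SCHEME,
    MODEL_A,
    MODEL_B,
    PAFScheme,
    assign_paf,
    derive_paf_scheme,
    evaluate_models,
    fit_prediction_model,
    predict_model_a,
    predict_model_b,
)
from opsfuel.synthetic import SimulationConfig, generate_cohort, published_course_specs


class TestSchemeDerivation:
    def test_quantile_definition_oracle(self):
        scheme = derive_paf_scheme([1.0, 2.0, 3.0, 4.0])
        # linear-interpolation quartiles of {1,2,3,4}
        assert scheme.cutpoints == pytest.approx((1.75, 2.5, 3.25))

    def test_identical_pals_rejected(self):
        with pytest.raises(ValueError):
            derive_paf_scheme([2.5] * 8)

    @given(
        st.lists(
            st.floats(1.2, 4.0, allow_nan=False), min_size=4, max_size=40, unique=True
        )
    )
    def test_always_three_ascending_cutpoints(self, pals):
        try:
            scheme = derive_paf_scheme(pals)
        except ValueError:
            return  # degenerate quartiles are rejected, not mangled
        c1, c2, c3 = scheme.cutpoints
        assert c1 < c2 < c3

    def test_cutpoints_must_increase(self):
        with pytest.raises(ValueError):
            PAFScheme(cutpoints=(2.4, 2.1, 2.75))


class TestAssignment:
    @pytest.mark.parametrize(
        "pal,paf", [(2.61, 2), (3.05, 3), (1.97, 0), (2.31, 1)]
    )
    def test_published_course_pals(self, pal, paf):
        assert assign_paf(pal, DEFAULT_SCHEME) == paf

    @pytest.mark.parametrize("pal,paf", [(2.10, 0), (2.40, 1), (2.75, 2), (2.751, 3)])
    def test_upper_bounds_inclusive(self, pal, paf):
        assert assign_paf(pal) == paf

    def test_published_grouping_reproduced_12_of_12(self):
        for row in reference.COURSE_ENERGY:
            assert assign_paf(row.pal, DEFAULT_SCHEME) == reference.PUBLISHED_PAF[row.name]


class TestPublishedModels:
    @pytest.mark.parametrize(
        "bm,paf,kcal", [(80.8, 3, 5528), (76.4, 2, 4610)]
    )
    def test_model_a_course_means(self, bm, paf, kcal):
        assert round(predict_model_a(bm, paf)) == kcal

    def test_model_a_intercept(self):
        assert predict_model_a(0.0, 0) == pytest.approx(-467.22)

    def test_model_b_squad_raids(self):
        assert round(predict_model_b(67.9, 2)) == 4921

    def test_model_b_weapons_training_full_precision(self):
        assert predict_model_b(69.3, 0) == pytest.approx(3574.607, abs=1e-3)

    def test_model_b_paf_slope(self):
        assert predict_model_b(70.0, 1) - predict_model_b(70.0, 0) == pytest.approx(
            716.49
        )

    def test_paf_outside_range_warns_but_computes(self):
        with pytest.warns(UserWarning, match="outside"):
            v = MODEL_A.predict(80.0, 4)
        assert v == pytest.approx(-467.22 + 47.97 * 80 + 706.33 * 4)

    def test_affine_mean_commutes(self, rng):
        # prediction at mean covariates equals mean of predictions
        bm = rng.uniform(70, 95, 50)
        paf = rng.integers(0, 4, 50).astype(float)
        preds = [predict_model_a(b, f) for b, f in zip(bm, paf)]
        assert np.mean(preds) == pytest.approx(
            predict_model_a(bm.mean(), paf.mean()), rel=1e-12
        )


def _cohort(seed=0, residual_sd=0.0, model=MODEL_A):
    cfg = SimulationConfig(
        courses=published_course_specs(with_paf=True),
        seed=seed,
        model_truth=model,
        residual_sd=residual_sd,
    )
    return generate_cohort(cfg)


class TestModelFitting:
    def test_noiseless_cohort_recovers_coefficients_exactly(self):
        cohort = _cohort()
        fit = fit_prediction_model(cohort, "body_mass", reference.PUBLISHED_PAF)
        assert fit.intercept == pytest.approx(MODEL_A.intercept, abs=1e-6)
        assert fit.beta_mass == pytest.approx(MODEL_A.beta_mass, rel=1e-8)
        assert fit.beta_paf == pytest.approx(MODEL_A.beta_paf, rel=1e-8)
        assert fit.see == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equations_oracle(self):
        cohort = _cohort(seed=3, residual_sd=500.0)
        fit = fit_prediction_model(cohort, "ffm", reference.PUBLISHED_PAF)
        X = np.column_stack(
            [
                np.ones(len(cohort)),
                [p.ffm_kg for p in cohort],
                [reference.PUBLISHED_PAF[p.course] for p in cohort],
            ]
        )
        y = np.array([p.tdee_kcal_d for p in cohort])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10 * abs(beta[0]) + 1e-8)
        assert fit.beta_mass == pytest.approx(beta[1], rel=1e-10)
        assert fit.beta_paf == pytest.approx(beta[2], rel=1e-10)
        resid = y - X @ beta
        assert fit.see == pytest.approx(
            np.sqrt(resid @ resid / (len(cohort) - 3)), rel=1e-10
        )

    def test_singular_design_rejected(self):
        cohort = _cohort()
        with pytest.raises(ValueError, match="singular"):
            fit_prediction_model(cohort, "body_mass", {p.course: 1 for p in cohort})

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_prediction_model(_cohort()[:3], "body_mass", [0, 1, 2])

    def test_recovery_unbiased_within_monte_carlo_error(self):
        # correctly calibrated unbiasedness check: the mean recovered
        # coefficient vector should sit within 3 Monte-Carlo SEs of truth
        rng = np.random.default_rng(11)
        n_rep = 200
        coefs = np.empty((n_rep, 3))
        specs = published_course_specs(with_paf=True)
        for i in range(n_rep):
            cfg = SimulationConfig(
                courses=specs, seed=int(rng.integers(2**31)),
                model_truth=MODEL_A, residual_sd=640.0,
            )
            fit = fit_prediction_model(
                generate_cohort(cfg), "body_mass", reference.PUBLISHED_PAF
            )
            coefs[i] = (fit.intercept, fit.beta_mass, fit.beta_paf)
        truth = np.array([MODEL_A.intercept, MODEL_A.beta_mass, MODEL_A.beta_paf])
        bias = coefs.mean(axis=0) - truth
        mc_se = coefs.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(bias) < 3 * mc_se + 1e-9)

    def test_recovery_bias_shrinks_with_cohort_size(self):
        # SEE converges to the residual sd as n grows
        import dataclasses

        rng = np.random.default_rng(5)
        sees = {}
        for scale in (1, 4):
            specs = tuple(
                dataclasses.replace(s, n=s.n * scale)
                for s in published_course_specs(with_paf=True)
            )
            vals = []
            for _ in range(40):
                cfg = SimulationConfig(
                    courses=specs, seed=int(rng.integers(2**31)),
                    model_truth=MODEL_A, residual_sd=640.0,
                )
                fit = fit_prediction_model(
                    generate_cohort(cfg), "body_mass", reference.PUBLISHED_PAF
                )
                vals.append(fit.see)
            sees[scale] = np.array(vals)
        assert abs(sees[4].mean() - 640) <= abs(sees[1].mean() - 640) + 5
        assert sees[4].std() < sees[1].std()


class TestEvaluation:
    def _toy(self):
        rows = [
            ("A", 80.0, 60.0, 4000.0), ("A", 82.0, 61.0, 4100.0),
            ("B", 75.0, 58.0, 4500.0), ("B", 77.0, 59.0, 4600.0),
            ("C", 90.0, 70.0, 5000.0), ("C", 88.0, 69.0, 5200.0),
        ]
        return [
            Participant(id=f"p{i}", course=c, body_mass_kg=bm, ffm_kg=ffm,
                        tdee_kcal_d=tdee)
            for i, (c, bm, ffm, tdee) in enumerate(rows)
        ]

    def test_perfect_predictions(self):
        # force measured == predicted: r = 1, SEE = 0, no course flagged
        people = self._toy()
        pafs = {"A": 0, "B": 1, "C": 2}
        for p in people:
            p.tdee_kcal_d = MODEL_A.predict(p.body_mass_kg, pafs[p.course])
        ev = evaluate_models(people, MODEL_A, pafs)
        assert ev.r == pytest.approx(1.0, abs=1e-9)
        assert ev.see == pytest.approx(0.0, abs=1e-6)
        assert (ev.per_course["p_bonferroni"].dropna() >= 0.999).all()

    def test_per_course_mean_differences_match_hand_oracle(self):
        people = self._toy()
        pafs = {"A": 0, "B": 1, "C": 2}
        ev = evaluate_models(people, MODEL_A, pafs)
        for course in ("A", "B", "C"):
            expected = np.mean(
                [
                    MODEL_A.intercept + MODEL_A.beta_mass * p.body_mass_kg
                    + MODEL_A.beta_paf * pafs[course] - p.tdee_kcal_d
                    for p in people if p.course == course
                ]
            )
            got = ev.per_course.set_index("course").loc[course, "mean_diff"]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_bonferroni_is_m_times_p_capped(self):
        ev = evaluate_models(self._toy(), MODEL_A, {"A": 0, "B": 1, "C": 2})
        tab = ev.per_course.dropna(subset=["p"])
        assert ev.n_courses_tested == 3
        for _, row in tab.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, 3 * row["p"]))

    def test_single_participant_course_excluded_with_warning(self):
        people = self._toy() + [
            Participant(id="solo", course="D", body_mass_kg=85.0, ffm_kg=66.0,
                        tdee_kcal_d=4800.0)
        ]
        with pytest.warns(UserWarning, match="n=1"):
            ev = evaluate_models(people, MODEL_A, {"A": 0, "B": 1, "C": 2, "D": 3})
        row = ev.per_course.set_index("course").loc["D"]
        assert np.isnan(row["p"])
        assert ev.n_courses_tested == 3
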