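"""Adjustment schemes: published coefficients, folds, fitting, application."""

import numpy as np
import pytest

from clockshift.adjustment import (
    AdjustmentModel,
    HyperparamGrid,
    apply_adjuster,
    fit_adjuster,
    loso_folds,
    median_baseline,
    published_total_age_model,
)
from clockshift.age_transform import inverse_transform_age, transform_age
from clockshift.io_formats import CellFractions, ClockPrediction, SampleAnnotation


def make_cohort(n, n_studies, rng, coefs=(0.9, -10.0, 10.0), intercept=0.0,
                noise_sd=0.1, pred_range=(25.0, 75.0)):
    """Cohort whose true ages follow an affine model of prediction and
    composition: CA = a*pred + b*Epi + c*IC + intercept + noise."""
    pred = rng.uniform(*pred_range, size=n)
    frac = rng.dirichlet((4.0, 1.0, 4.0), size=n)
    a, b, c = coefs
    ages = a * pred + b * frac[:, 0] + c * frac[:, 2] + intercept
    ages = np.clip(ages + rng.normal(0, noise_sd, n), 0.0, None)
    ids = [f"s{i}" for i in range(n)]
    predictions = [ClockPrediction(s, p) for s, p in zip(ids, pred)]
    annotations = [
        SampleAnnotation(s, float(age), f"study{i % n_studies}", "saliva")
        for i, (s, age) in enumerate(zip(ids, ages))
    ]
    fractions = CellFractions(ids, ["Epi", "Fib", "IC"], frac)
    return predictions, annotations, fractions


class TestPublishedModels:
    def test_untransformed_pure_epithelial(self):
        model = published_total_age_model(transformed=False)
        fr = CellFractions(["x"], ["Epi", "Fib", "IC"], [[1.0, 0.0, 0.0]])
        out = apply_adjuster(model, [ClockPrediction("x", 50.0)], fr)
        assert out[0] == pytest.approx(0.85 * 50 - 11.54 - 15.76, abs=1e-9)

    def test_untransformed_pure_immune(self):
        model = published_total_age_model(transformed=False)
        fr = CellFractions(["x"], ["Epi", "Fib", "IC"], [[0.0, 0.0, 1.0]])
        out = apply_adjuster(model, [ClockPrediction("x", 50.0)], fr)
        assert out[0] == pytest.approx(42.5 + 10.56 - 15.76, abs=1e-9)

    def test_pure_epithelial_offset_is_constant_in_prediction(self):
        """For a fully epithelial sample the raw clock runs high by the sum
        of the Epi coefficient and intercept magnitudes, independent of the
        prediction itself."""
        model = published_total_age_model(transformed=False)
        fr = CellFractions(["x"], ["Epi", "Fib", "IC"], [[1.0, 0.0, 0.0]])
        for p in (10.0, 50.0, 93.7):
            out = apply_adjuster(model, [ClockPrediction("x", p)], fr)
            assert 0.85 * p - out[0] == pytest.approx(11.54 + 15.76, abs=1e-9)

    def test_transformed_model_hand_example(self):
        model = published_total_age_model(transformed=True)
        fr = CellFractions(["x"], ["Epi", "Fib", "IC"], [[0.0, 0.0, 1.0]])
        out = apply_adjuster(model, [ClockPrediction("x", 41.0)], fr)
        # f(41) = 1, so output = f_inv(0.93 + 1.05 - 1.18) = f_inv(0.80)
        assert out[0] == pytest.approx(inverse_transform_age(0.80), abs=1e-9)
        assert out[0] == pytest.approx(36.8, abs=1e-9)


class TestLosoFolds:
    def test_partition_and_sizes(self):
        ann = [
            SampleAnnotation(f"s{i}", 30, "B" if i < 2 else "A", "saliva")
            for i in range(5)
        ]
        folds = loso_folds(ann)
        assert [len(test) for _, test in folds] == [3, 2]  # sorted: A then B
        tested = [s for _, test in folds for s in test]
        assert sorted(tested) == sorted(a.sample_id for a in ann)
        for train, test in folds:
            assert not set(train) & set(test)

    def test_single_study_rejected(self):
        ann = [SampleAnnotation("s1", 30, "A", "saliva")]
        with pytest.raises(ValueError, match="2 distinct"):
            loso_folds(ann)

    def test_order_stable(self):
        ann = [
            SampleAnnotation(f"s{i}", 30, st, "saliva")
            for i, st in enumerate(["C", "A", "B", "A"])
        ]
        assert loso_folds(ann) == loso_folds(list(ann))


class TestMedianBaseline:
    @pytest.mark.parametrize(
        "ages, expected", [([10, 20, 90], 20), ([10, 20], 15), ([42], 42)]
    )
    def test_values(self, ages, expected):
        assert median_baseline(ages) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_baseline([])


class TestApply:
    def test_none_is_identity(self):
        out = apply_adjuster(AdjustmentModel("none"), [ClockPrediction("a", 37.2)])
        assert out[0] == 37.2

    def test_delta_subtracts_fitted_residual(self):
        model = AdjustmentModel(
            "delta", coefficients={"Epi": 20.0, "IC": -5.0, "intercept": 0.0}
        )
        fr = CellFractions(["a"], ["Epi", "Fib", "IC"], [[1.0, 0.0, 0.0]])
        out = apply_adjuster(model, [ClockPrediction("a", 60.0)], fr)
        assert out[0] == pytest.approx(40.0)

    def test_delta_sign_flip(self):
        model = AdjustmentModel(
            "delta", coefficients={"Epi": 20.0, "IC": -5.0, "intercept": 0.0}
        )
        fr = CellFractions(["a"], ["Epi", "Fib", "IC"], [[1.0, 0.0, 0.0]])
        out = apply_adjuster(
            model, [ClockPrediction("a", 60.0)], fr, delta_sign="add"
        )
        assert out[0] == pytest.approx(80.0)

    def test_missing_required_feature_raises(self):
        model = published_total_age_model(False)
        with pytest.raises(ValueError):
            apply_adjuster(model, [ClockPrediction("a", 60.0)], None)


class TestFit:
    def test_ols_matches_normal_equations(self, rng):
        """alpha = 0 must reproduce the closed-form least-squares solution."""
        preds, ann, frac = make_cohort(120, 3, rng, noise_sd=0.0)
        grid = HyperparamGrid(l1_ratios=(0.0,), alphas=(0.0,))
        model = fit_adjuster("total", False, preds, ann, frac, grid)
        X = np.column_stack([
            [p.predicted_age for p in preds],
            frac.column("Epi"),
            frac.column("IC"),
            np.ones(len(preds)),
        ])
        y = np.array([a.age for a in ann])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        got = [model.coefficients[k] for k in ("prediction", "Epi", "IC", "intercept")]
        np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_parameter_recovery_with_default_grid(self, rng):
        preds, ann, frac = make_cohort(500, 4, rng, noise_sd=0.1)
        model = fit_adjuster("total", False, preds, ann, frac)
        assert model.coefficients["prediction"] == pytest.approx(0.9, abs=0.05)
        assert model.coefficients["Epi"] == pytest.approx(-10.0, abs=0.05)
        assert model.coefficients["IC"] == pytest.approx(10.0, abs=0.05)

    def test_scheme_none_is_empty_identity(self):
        model = fit_adjuster("none", False, [], [], None)
        assert model.coefficients == {}
        out = apply_adjuster(model, [ClockPrediction("a", 12.3)])
        assert out[0] == 12.3

    def test_single_study_rejected(self, rng):
        preds, ann, frac = make_cohort(30, 1, rng)
        with pytest.raises(ValueError):
            fit_adjuster("total", False, preds, ann, frac)

    def test_missing_fraction_columns_rejected(self, rng):
        preds, ann, _ = make_cohort(30, 2, rng)
        bad = CellFractions(
            [p.sample_id for p in preds], ["A", "B"],
            np.full((30, 2), 0.5),
        )
        with pytest.raises(ValueError, match="Epi"):
            fit_adjuster("total", False, preds, ann, bad)

    def test_selection_invariant_to_sample_order(self, rng):
        preds, ann, frac = make_cohort(90, 3, rng)
        grid = HyperparamGrid(l1_ratios=(0.0, 0.5), alphas=(0.0, 1e-2, 1.0))
        m1 = fit_adjuster("total", False, preds, ann, frac, grid)
        order = rng.permutation(len(preds))
        m2 = fit_adjuster(
            "total", False,
            [preds[i] for i in order], [ann[i] for i in order], frac, grid,
        )
        assert (m1.alpha, m1.l1_ratio) == (m2.alpha, m2.l1_ratio)
        for k, v in m1.coefficients.items():
            assert m2.coefficients[k] == pytest.approx(v, abs=1e-8)

    def test_transformed_and_raw_coincide_on_linear_branch(self, rng):
        """When every age and prediction lies above the knot and the true
        relation is affine, fitting in transformed space is an exact
        reparameterization: the applied outputs must coincide."""
        preds, ann, frac = make_cohort(
            80, 2, rng, noise_sd=0.0, pred_range=(40.0, 90.0)
        )
        assert min(a.age for a in ann) > 20
        grid = HyperparamGrid(l1_ratios=(0.0,), alphas=(0.0,))
        raw = fit_adjuster("total", False, preds, ann, frac, grid)
        tr = fit_adjuster("total", True, preds, ann, frac, grid)
        out_raw = apply_adjuster(raw, preds, frac)
        out_tr = apply_adjuster(tr, preds, frac)
        np.testing.assert_allclose(out_tr, out_raw, atol=1e-8)

    def test_affine_monotone_when_no_fraction_coefficients(self, rng):
        preds, ann, _ = make_cohort(60, 2, rng, coefs=(0.8, 0.0, 0.0),
                                    intercept=5.0, noise_sd=0.05)
        grid = HyperparamGrid(l1_ratios=(0.0,), alphas=(0.0,))
        model = fit_adjuster("simple", False, preds, ann, None, grid)
        assert model.coefficients["prediction"] > 0
        grid_pred = [ClockPrediction(f"g{i}", p) for i, p in enumerate(range(25, 75, 5))]
        out = apply_adjuster(model, grid_pred)
        assert np.all(np.diff(out) > 0)


class TestGridAndSerialization:
    def test_default_grid_matches_printed_search_space(self):
        grid = HyperparamGrid()
        np.testing.assert_allclose(grid.l1_ratios, np.arange(0.0, 1.0, 0.01))
        assert grid.alphas == (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 0.0, 1.0, 10.0, 100.0)
        # alpha = 0 collapses the l1_ratio axis: one OLS candidate
        cands = grid.candidates()
        assert len(cands) == 8 * 100 + 1

    def test_model_round_trip(self, tmp_path):
        model = AdjustmentModel(
            "total", True,
            {"prediction": 0.93, "Epi": -1.14, "IC": 1.05, "intercept": -1.18},
            alpha=1e-3, l1_ratio=0.25,
        )
        path = tmp_path / "m.json"
        model.save(path)
        back = AdjustmentModel.load(path)
        assert back == model

    def test_invalid_scheme_and_transform_combinations(self):
        with pytest.raises(ValueError):
            AdjustmentModel("delta", transformed=True)
        with pytest.raises(ValueError):
            AdjustmentModel("none", coefficients={"intercept": 1.0})
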