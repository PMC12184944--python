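"""Evaluator: parameter prediction, centile/score queries and their
inversion, centile curves, batch tables, raw-scale transforms, clamping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normcard import (DistributionParams, FixtureSpec, QueryError, RangeError,
                      batch_evaluate, centile, centile_curves, family_cdf,
                      make_model, predict_parameters, score, slj_like_model)
from normcard.links import apply_inverse_link
from normcard.model import ParameterBlock, NormModel
from oracles import basis_matrix_oracle
from normcard.splines import build_knots


class TestPredictParameters:
    def test_intercept_only_log_link(self, no_model):
        blocks = dict(no_model.blocks)
        blocks["sigma"] = ParameterBlock("log", -1.0)
        m = NormModel(no_model.family_id, no_model.outcome,
                      no_model.predictors, blocks)
        p = predict_parameters(m, {"x1": 0.5})
        assert p.sigma == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_mu_from_published_linear_coefficients_spline_zeroed(self, slj_model):
        # zero the mu spline so only the printed intercept and slope act
        mu = slj_model.blocks["mu"]
        zeroed = ParameterBlock(
            "log", mu.intercept, mu.linear_terms,
            tuple(type(t)(t.predictor_name, t.degree, t.range, t.n_intervals,
                          np.zeros_like(t.coefficients))
                  for t in mu.spline_terms))
        blocks = dict(slj_model.blocks)
        blocks["mu"] = zeroed
        m = NormModel(slj_model.family_id, slj_model.outcome,
                      slj_model.predictors, blocks)
        p = predict_parameters(m, {"nage": np.sqrt(10)})
        assert p.mu == pytest.approx(np.exp(3.60 + 0.42 * np.sqrt(10)), rel=1e-12)

    def test_matches_step_by_step_oracle_on_grid(self, bct_spline_model):
        m = bct_spline_model
        grid = np.linspace(0.0, 1.0, 20)
        for x in grid:
            got = predict_parameters(m, {"x1": float(x)})
            for pname, block in m.blocks.items():
                eta = block.intercept
                for name, coef in block.linear_terms:
                    eta += coef * x
                for t in block.spline_terms:
                    kv = build_knots(t.range, t.n_intervals, t.degree)
                    basis = basis_matrix_oracle([x], kv.knots, t.degree,
                                                interior_hi=t.range[1])
                    eta += float((basis @ t.coefficients)[0])
                want = apply_inverse_link(block.link_id, eta)
                assert getattr(got, pname) == pytest.approx(want, rel=1e-12)

    def test_missing_predictor_named(self, bct_spline_model):
        with pytest.raises(QueryError, match="x1"):
            predict_parameters(bct_spline_model, {})

    def test_out_of_range_hard_error_and_optin_clamp(self, bct_spline_model):
        with pytest.raises(RangeError, match="x1"):
            predict_parameters(bct_spline_model, {"x1": 1.5})
        clamped = predict_parameters(bct_spline_model, {"x1": 1.5}, clamp=True)
        edge = predict_parameters(bct_spline_model, {"x1": 1.0})
        assert clamped == edge


class TestCentileAndScore:
    def test_gaussian_median(self, no_model):
        assert centile(no_model, 100.0, {"x1": 0.5}) == pytest.approx(50.0)

    def test_gaussian_one_sd_above(self, no_model):
        want = 100.0 * stats.norm.cdf(1.0)  # 84.13...
        assert centile(no_model, 115.0, {"x1": 0.5}) == pytest.approx(
            want, abs=1e-9)
        assert round(centile(no_model, 115.0, {"x1": 0.5}), 2) == 84.13

    def test_score_at_median(self, no_model):
        assert score(no_model, 50.0, {"x1": 0.5}) == pytest.approx(100.0)

    def test_centile_equals_cdf_of_predicted_distribution(self, slj_model):
        q = {"nage": np.sqrt(10)}
        params = predict_parameters(slj_model, q)
        got = centile(slj_model, 140.0, q)
        assert got == pytest.approx(100.0 * family_cdf("BCT", 140.0, params),
                                    rel=1e-14)

    def test_raw_age_equals_transformed_nage_query(self, slj_model):
        assert centile(slj_model, 140.0, {"age": 10.0}) == centile(
            slj_model, 140.0, {"nage": np.sqrt(10.0)})

    def test_supplying_both_scales_is_an_error(self, slj_model):
        with pytest.raises(QueryError, match="more than once"):
            centile(slj_model, 140.0, {"age": 10.0, "nage": 3.16})

    def test_mutual_inversion_random_cases(self, all_family_models):
        rng = np.random.default_rng(77)
        for m in all_family_models.values():
            for _ in range(25):
                q = {"x1": float(rng.uniform(0, 1))}
                c = float(rng.uniform(1, 99))
                y = score(m, c, q)
                assert centile(m, y, q) == pytest.approx(c, rel=1e-8)

    def test_centile_strictly_increasing_in_score(self, slj_model):
        q = {"age": 12.0}
        ys = np.linspace(80, 220, 40)
        cs = [centile(slj_model, y, q) for y in ys]
        assert np.all(np.diff(cs) > 0)

    def test_centile_out_of_bounds_rejected(self, no_model):
        with pytest.raises(QueryError):
            score(no_model, 0.0, {"x1": 0.5})
        with pytest.raises(QueryError):
            score(no_model, 100.0, {"x1": 0.5})


class TestCentileCurves:
    def test_nine_non_crossing_curves(self, slj_model):
        t = centile_curves(slj_model, "nage", grid_size=40)
        assert t.scores.shape == (40, 9)
        assert np.all(np.diff(t.scores, axis=1) > 0)

    def test_intercept_only_model_gives_horizontal_lines(self, no_model):
        blocks = {k: ParameterBlock(v.link_id, v.intercept)
                  for k, v in no_model.blocks.items()}
        m = NormModel(no_model.family_id, no_model.outcome,
                      no_model.predictors, blocks)
        t = centile_curves(m, "x1", grid_size=15)
        np.testing.assert_allclose(np.ptp(t.scores, axis=0), 0.0, atol=1e-10)

    def test_two_predictor_curves_equal_pointwise_scores(self):
        m = make_model(FixtureSpec(family_id="BCCG", seed=9, n_predictors=2,
                                   splines={"mu": (3, 6)}))
        t = centile_curves(m, "x1", levels=(25.0, 50.0, 75.0), grid_size=7,
                           fixed={"x2": 0.5})
        for i, x in enumerate(t.x):
            for j, lev in enumerate(t.levels):
                want = score(m, lev, {"x1": float(x), "x2": 0.5})
                assert t.scores[i, j] == pytest.approx(want, rel=1e-12)

    def test_single_point_grid_allowed(self, slj_model):
        t = centile_curves(slj_model, "nage", grid_size=1)
        assert t.scores.shape[0] == 1

    def test_raw_scale_carried_for_transformed_predictor(self, slj_model):
        t = centile_curves(slj_model, "nage", grid_size=10)
        np.testing.assert_allclose(t.x_raw, t.x ** 2, rtol=1e-12)
        assert t.raw_name == "age"
        frame = t.to_frame()
        assert list(frame.columns[:2]) == ["age", "nage"]

    def test_explicit_display_transform(self, slj_model):
        t = centile_curves(slj_model, "nage", grid_size=5,
                           x_display_transform=lambda x: x ** 2)
        np.testing.assert_allclose(t.x_raw, t.x ** 2)

    def test_unknown_predictor_rejected(self, slj_model):
        with pytest.raises(QueryError, match="height"):
            centile_curves(slj_model, "height")

    def test_missing_fixed_predictor_rejected(self):
        m = make_model(FixtureSpec(family_id="NO", seed=4, n_predictors=2))
        with pytest.raises(QueryError, match="x2"):
            centile_curves(m, "x1")


class TestBatchEvaluate:
    def test_three_rows_match_scalar_calls(self, no_model):
        table = pd.DataFrame({"x1": [0.1, 0.5, 0.9],
                              "score": [85.0, 100.0, 115.0]})
        out = batch_evaluate(no_model, table, mode="centile")
        for i, row in table.iterrows():
            assert out.loc[i, "centile"] == pytest.approx(
                centile(no_model, row["score"], {"x1": row["x1"]}))

    def test_partial_failure_policy(self, bct_spline_model):
        table = pd.DataFrame({"x1": [0.2, 5.0, 0.8],
                              "score": [100.0, 100.0, 100.0]})
        out = batch_evaluate(bct_spline_model, table, mode="centile")
        assert out["centile"].notna().tolist() == [True, False, True]
        assert "outside valid range" in out.loc[1, "note"]

    def test_score_mode_row_order_preserved(self, slj_model):
        table = pd.DataFrame({"age": [10.0, 10.5, 16.0],
                              "centile": [90.0, 45.0, 50.0]})
        out = batch_evaluate(slj_model, table, mode="score")
        assert list(out["age"]) == [10.0, 10.5, 16.0]
        for i, row in table.iterrows():
            assert out.loc[i, "score"] == pytest.approx(
                score(slj_model, row["centile"], {"age": row["age"]}))

    def test_large_random_table_equals_mapped_scalars(self, no_model):
        rng = np.random.default_rng(31)
        table = pd.DataFrame({"x1": rng.uniform(0, 1, 1000),
                              "score": rng.uniform(60, 140, 1000)})
        out = batch_evaluate(no_model, table, mode="centile")
        want = [centile(no_model, s, {"x1": x})
                for x, s in zip(table["x1"], table["score"])]
        np.testing.assert_allclose(out["centile"], want, rtol=1e-12)

    def test_missing_required_column(self, no_model):
        with pytest.raises(QueryError, match="score"):
            batch_evaluate(no_model, pd.DataFrame({"x1": [0.5]}), mode="centile")


def test_probability_integral_transform_uniformity(slj_model):
    """Scores drawn from the model's own law yield uniform centiles."""
    from normcard import simulate_scores

    q = {"age": 11.0}
    y = simulate_scores(slj_model, q, 10_000, seed=99)
    u = np.array([centile(slj_model, float(v), q) for v in y[:2000]]) / 100.0
    assert stats.kstest(u, "uniform").pvalue > 0.01
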