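"""Additive edge-curve model: fitting, prediction, contrasts, Moran's I."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import BSpline

from edgetherm.curve_model import (ExtrapolationError, RankDeficiencyError,
                                   combine_se, edge_interior_contrast,
                                   fit_edge_curve, morans_i, predict_partial,
                                   variant_contrast)
from edgetherm.synthetic_landscape import sigmoid

from conftest import make_points


class TestFitting:
    def test_constant_response_flat_curve_and_zero_scene_effects(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: np.full(d.size, 17.5))
        model = fit_edge_curve(pts)
        curve = predict_partial(model, np.arange(-200.0, 401.0, 20.0))
        assert curve["fit"].max() - curve["fit"].min() < 1e-9
        assert np.abs(model.coefficients[model.slices["scene"]]).max() < 1e-4

    def test_scene_offsets_absorbed_by_random_effect(self, rng):
        pts = make_points(rng, offsets=[-5.0, 5.0, 2.0, -2.0],
                          tsurf_fn=lambda d, e: np.full(d.size, 20.0))
        model = fit_edge_curve(pts)
        curve = predict_partial(model, np.arange(-200.0, 401.0, 10.0))
        assert curve["fit"].max() - curve["fit"].min() < 1e-6

    def test_single_distance_value_rank_deficiency(self, rng):
        pts = make_points(rng)
        pts["dist_m"] = 100.0
        with pytest.raises(RankDeficiencyError, match="distance"):
            fit_edge_curve(pts)

    def test_requires_two_sxo(self, rng):
        pts = make_points(rng, n_scenes=1)
        with pytest.raises(ValueError):
            fit_edge_curve(pts)

    def test_penalized_normal_equations_hold(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - 3.0 * sigmoid(d / 60.0)
                          + 0.002 * e + rng.normal(0, 0.5, d.size))
        model = fit_edge_curve(pts)
        lhs = model.xty - model.xtx @ model.coefficients
        rhs = model.penalty @ model.coefficients
        scale = max(np.abs(rhs).max(), 1.0)
        assert np.abs(lhs - rhs).max() / scale < 1e-6

    def test_predictions_invariant_to_elevation_shift(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - 2.0 * sigmoid(d / 80.0)
                          - 0.0065 * (e - 300.0) + rng.normal(0, 0.3, d.size))
        m1 = fit_edge_curve(pts)
        m2 = fit_edge_curve(pts.assign(elev_m=pts["elev_m"] + 123.0))
        np.testing.assert_allclose(predict_partial(m1)["fit"],
                                   predict_partial(m2)["fit"], atol=1e-8)

    def test_infinite_distance_penalty_linearizes_curve(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - 3.0 * sigmoid(d / 60.0)
                          + rng.normal(0, 0.5, d.size))
        model = fit_edge_curve(pts, lambdas={"dist": 1e12, "elev": 1.0,
                                             "scene": 1.0})
        fit = predict_partial(model, np.arange(-200.0, 401.0, 25.0))["fit"]
        assert np.abs(np.diff(fit, 2)).max() < 1e-6


class TestPrediction:
    def test_default_grid_is_701_metres(self, rng):
        pts = make_points(rng)
        curve = predict_partial(fit_edge_curve(pts))
        assert len(curve) == 701
        assert curve["d"].iloc[0] == -200.0 and curve["d"].iloc[-1] == 500.0

    def test_prediction_equals_manual_basis_row_product(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - 3.0 * sigmoid(d / 60.0)
                          + rng.normal(0, 0.5, d.size))
        model = fit_edge_curve(pts)
        d0 = 123.0
        row = np.zeros(model.coefficients.size)
        row[0] = 1.0
        B = BSpline.design_matrix(np.array([d0]), model.dist_term.knots,
                                  3).toarray()
        row[model.slices["dist"]] = (B @ model.dist_term.transform)[0]
        Be = BSpline.design_matrix(np.array([model.ref_elev]),
                                   model.elev_term.knots, 3).toarray()
        row[model.slices["elev"]] = (Be @ model.elev_term.transform)[0]
        idx = model.scene_levels.index(model.ref_scene)
        row[model.slices["scene"].start + idx] = 1.0
        manual = float(row @ model.coefficients)
        got = float(predict_partial(model, [d0])["fit"].iloc[0])
        assert got == pytest.approx(manual, rel=1e-12)

    def test_se_symmetric_under_symmetric_design(self, rng):
        # constant elevation -> term dropped; symmetric distances
        d = np.concatenate([np.tile([-300., -150., 150., 300.], 100)])
        frames = []
        for s in range(2):
            frames.append(pd.DataFrame({
                "scene_id": f"S{s}", "overpass_id": "O0", "dist_m": d,
                "tsurf_c": 20.0 + rng.normal(0, 0.5, d.size),
                "elev_m": 300.0}))
        model = fit_edge_curve(pd.concat(frames, ignore_index=True))
        curve = predict_partial(model, [-150.0, 150.0])
        assert curve["se"].iloc[0] == pytest.approx(curve["se"].iloc[1],
                                                    rel=1e-6)

    def test_extrapolation_raises(self, rng):
        pts = make_points(rng)
        model = fit_edge_curve(pts)
        with pytest.raises(ExtrapolationError):
            predict_partial(model, [1500.0])


class TestContrast:
    def test_identical_distances_zero_contrast(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - sigmoid(d / 60.0))
        model = fit_edge_curve(pts)
        assert edge_interior_contrast(model, 100.0, 100.0).delta_c == 0.0

    def test_se_rules_arithmetic(self):
        # SE_e=0.04, SE_i=0.09: the printed rule vs conventional quadrature
        assert combine_se(0.04, 0.09, "as-printed") == pytest.approx(
            np.sqrt(0.13))
        assert combine_se(0.04, 0.09, "quadrature") == pytest.approx(
            np.sqrt(0.0097))

    def test_both_rules_carried_on_result(self, rng):
        pts = make_points(rng, tsurf_fn=lambda d, e: 20.0 - sigmoid(d / 60.0)
                          + rng.normal(0, 0.3, d.size))
        c = edge_interior_contrast(fit_edge_curve(pts), 30.0, 400.0)
        assert c.se_delta == c.se_as_printed
        assert c.se_as_printed > c.se_quadrature > 0
        assert c.se_cov > 0

    def test_wide_contrast_dominates_for_long_sigmoid_scales(self, rng):
        # |T(50)-T(1000)| >= |T(30)-T(500)| holds for lam >~ 150 (analytic);
        # for short scales the 30->50 m step on the steep part of the curve
        # outweighs the interior tail and the ordering genuinely reverses.
        s = sigmoid
        for lam in (150.0, 175.0, 200.0):
            assert abs(s(1000 / lam) - s(50 / lam)) >= abs(
                s(500 / lam) - s(30 / lam))
        assert abs(s(1000 / 50.0) - s(50 / 50.0)) < abs(
            s(500 / 50.0) - s(30 / 50.0))
        pts = make_points(rng, n_per_scene=600, dist_range=(-1000.0, 1000.0),
                          tsurf_fn=lambda d, e: 20.0 - 3.0 * sigmoid(d / 175.0)
                          + rng.normal(0, 0.5, d.size))
        model = fit_edge_curve(pts)
        wide = variant_contrast(model, 50.0, 1000.0)
        narrow = edge_interior_contrast(model, 30.0, 500.0)
        assert abs(wide.delta_c) >= abs(narrow.delta_c)


class TestMoransI:
    def test_null_expectation_is_minus_one_over_n_minus_one(self, rng):
        n = 11
        coords = rng.uniform(0, 100, size=(n, 2))
        mi = morans_i(rng.normal(size=n), coords, n_permutations=19, seed=0)
        assert mi.expected_i == pytest.approx(-1.0 / (n - 1))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            morans_i(np.arange(5.0), rng.uniform(0, 1, (5, 2)))

    def test_smooth_gradient_strongly_positive(self, rng):
        coords = rng.uniform(0, 1000, size=(400, 2))
        resid = coords[:, 0] / 1000.0
        mi = morans_i(resid, coords, seed=0, n_permutations=999)
        assert mi.i > 0
        assert mi.p_value <= 0.001

    def test_identical_residuals_flagged(self, rng):
        coords = rng.uniform(0, 100, size=(50, 2))
        mi = morans_i(np.ones(50), coords, seed=0, n_permutations=19)
        assert mi.degenerate
        assert np.isnan(mi.i)

    def test_subsetting_respects_max_points(self, rng):
        coords = rng.uniform(0, 100, size=(500, 2))
        mi = morans_i(rng.normal(size=500), coords, max_points=100, seed=0,
                      n_permutations=19)
        assert mi.n_used == 100
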