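"""Per-SxO slopes, Hampel filtering, and the IVW quadratic meta-regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from edgetherm.slope_meta import (InsufficientDataError, SceneSlope,
                                  SlopeRejection, compute_scene_slopes,
                                  hampel_filter, ivw_quadratic,
                                  no_outlier_variant, scene_slope,
                                  subset_cooling)


def _scene_frame(d, y, elev=None, scene="S0", overpass="O0"):
    return pd.DataFrame({"scene_id": scene, "overpass_id": overpass,
                         "dist_m": d, "tsurf_c": y,
                         "elev_m": elev if elev is not None
                         else np.full(len(d), 300.0)})


def _slope(beta, var=0.01, t=20.0, sid="S0", oid="O0", n=50):
    return SceneSlope(sid, oid, beta=beta, var_beta=var, n_obs=n,
                      scene_mean_t=t)


class TestSceneSlope:
    def test_exact_log_linear_truth(self):
        d = np.array([30.0, 100.0, 300.0, 900.0])
        y = 25.0 - 2.0 * np.log10(d)
        s = scene_slope(_scene_frame(d, y))
        assert isinstance(s, SceneSlope)
        assert s.beta == pytest.approx(-2.0, abs=1e-10)
        assert s.var_beta == pytest.approx(0.0, abs=1e-12)

    def test_constant_response_zero_slope(self):
        d = np.array([30.0, 100.0, 300.0, 900.0, 50.0])
        s = scene_slope(_scene_frame(d, np.full(5, 21.0)))
        assert s.beta == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            d = 10.0 ** rng.uniform(np.log10(30), 3, n)
            elev = rng.normal(300, 60, n)
            y = 20.0 - 1.5 * np.log10(d) - 0.006 * elev + rng.normal(0, 1, n)
            s = scene_slope(_scene_frame(d, y, elev))
            X = sm.add_constant(np.column_stack([np.log10(d), elev]))
            ref = sm.OLS(y, X).fit()
            assert s.beta == pytest.approx(ref.params[1], rel=1e-8)
            assert s.var_beta == pytest.approx(ref.bse[1] ** 2, rel=1e-8)

    def test_too_few_observations_rejected_not_raised(self):
        d = np.array([30.0, 100.0, 300.0])
        res = scene_slope(_scene_frame(d, np.zeros(3)))
        assert isinstance(res, SlopeRejection)
        assert "fewer than 4" in res.reason

    def test_singular_design_rejected(self):
        d = np.full(6, 100.0)
        res = scene_slope(_scene_frame(d, np.arange(6.0)))
        assert isinstance(res, SlopeRejection)
        assert res.reason == "singular design"

    def test_out_of_forest_points_refused(self):
        d = np.array([-30.0, 100.0, 300.0, 900.0])
        with pytest.raises(ValueError):
            scene_slope(_scene_frame(d, np.zeros(4)))

    def test_scene_mean_uses_all_points_inside_and_out(self, rng):
        d = np.array([-500.0, -50.0, 40.0, 90.0, 200.0, 800.0])
        y = np.array([30.0, 29.0, 25.0, 24.0, 23.0, 22.0])
        pts = _scene_frame(d, y)
        slopes, _ = compute_scene_slopes(pts)
        assert slopes[0].scene_mean_t == pytest.approx(y.mean())
        assert slopes[0].n_obs == 4  # regression on in-forest points only


class TestHampel:
    def test_symmetric_small_set_untouched(self):
        slopes = [_slope(b) for b in (-1.0, 0.0, 1.0)]
        kept, removed = hampel_filter(slopes)
        assert len(kept) == 3 and not removed

    def test_degenerate_mad_removes_everything_off_median(self):
        slopes = [_slope(b) for b in (0.0, 0.0, 0.0, 0.0, 7.0)]
        kept, removed = hampel_filter(slopes)
        assert [s.beta for s in removed] == [7.0]
        assert all(s.beta == 0.0 for s in kept)

    def test_injected_outlier_exactly_removed(self, rng):
        base = rng.normal(0.0, 1.0, 500)
        med = np.median(base)
        mad = np.median(np.abs(base - med))
        inject = med + 10.0 * mad
        slopes = [_slope(b, sid=f"S{i}") for i, b in enumerate(base)]
        slopes.append(_slope(inject, sid="SX"))
        kept, removed = hampel_filter(slopes)
        assert "SX" in {s.scene_id for s in removed}
        # every kept point lies inside the post-injection interval
        betas = np.append(base, inject)
        med2 = np.median(betas)
        mad2 = np.median(np.abs(betas - med2))
        for s in kept:
            assert abs(s.beta - med2) <= 3 * mad2 + 1e-12

    def test_mean_absolute_deviation_variant(self):
        slopes = [_slope(b) for b in (-1.0, 0.0, 1.0, 30.0)]
        kept_mad, _ = hampel_filter(slopes, scale="mad")
        kept_mean, _ = hampel_filter(slopes, scale="mean")
        # the mean-based scale is inflated by the outlier itself
        assert len(kept_mean) >= len(kept_mad)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=40))
    def test_partition_and_interval_property(self, betas):
        slopes = [_slope(b, sid=f"S{i}") for i, b in enumerate(betas)]
        kept, removed = hampel_filter(slopes)
        assert len(kept) + len(removed) == len(slopes)
        med = np.median(betas)
        mad = np.median(np.abs(np.asarray(betas) - med))
        for s in kept:
            assert abs(s.beta - med) <= 3 * mad + 1e-12
        for s in removed:
            assert abs(s.beta - med) > 3 * mad


class TestIVW:
    def test_equal_weights_reduce_to_ols(self, rng):
        t = rng.uniform(0, 35, 30)
        beta = 0.5 - 0.1 * t + 0.003 * t ** 2 + rng.normal(0, 0.2, 30)
        slopes = [_slope(b, var=0.04, t=tt, sid=f"S{i}")
                  for i, (b, tt) in enumerate(zip(beta, t))]
        fit = ivw_quadratic(slopes)
        ref = sm.OLS(beta, np.column_stack([np.ones(30), t, t ** 2])).fit()
        np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        t = rng.uniform(0, 35, 40)
        var = rng.uniform(0.01, 0.4, 40)
        beta = 0.5 - 0.1 * t + 0.003 * t ** 2 + rng.normal(0, np.sqrt(var))
        slopes = [_slope(b, var=v, t=tt, sid=f"S{i}")
                  for i, (b, v, tt) in enumerate(zip(beta, var, t))]
        fit = ivw_quadratic(slopes)
        X = np.column_stack([np.ones(40), t, t ** 2])
        ref = sm.WLS(beta, X, weights=1.0 / var).fit()
        np.testing.assert_allclose(fit.coef, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)

    def test_noiseless_quadratic_recovered_exactly(self):
        t = np.linspace(1, 35, 20)
        slopes = [_slope(0.002 * tt ** 2, var=1e-8, t=tt, sid=f"S{i}")
                  for i, tt in enumerate(t)]
        fit = ivw_quadratic(slopes)
        assert fit.b2 == pytest.approx(0.002, abs=1e-8)
        assert fit.b0 == pytest.approx(0.0, abs=1e-8)
        assert fit.b1 == pytest.approx(0.0, abs=1e-8)
        assert fit.weighted_r2 == pytest.approx(1.0, abs=1e-6)

    def test_variance_rescaling_leaves_coefficients_unchanged(self, rng):
        t = rng.uniform(0, 35, 25)
        beta = rng.normal(0, 1, 25)
        var = rng.uniform(0.01, 0.5, 25)
        s1 = [_slope(b, var=v, t=tt, sid=f"S{i}")
              for i, (b, v, tt) in enumerate(zip(beta, var, t))]
        s2 = [_slope(b, var=37.0 * v, t=tt, sid=f"S{i}")
              for i, (b, v, tt) in enumerate(zip(beta, var, t))]
        f1, f2 = ivw_quadratic(s1), ivw_quadratic(s2)
        np.testing.assert_allclose(f1.coef, f2.coef, rtol=1e-12)
        assert f1.weighted_r2 == pytest.approx(f2.weighted_r2, rel=1e-12)

    def test_insufficient_scenes_raise(self):
        with pytest.raises(InsufficientDataError):
            ivw_quadratic([_slope(0.1), _slope(0.2), _slope(0.3)])


class TestVariants:
    def test_cooling_subset_sign_rule(self):
        slopes = [_slope(-0.5, sid="A"), _slope(0.5, sid="B"),
                  _slope(-0.01, sid="C"), _slope(0.0, sid="D")]
        kept = subset_cooling(slopes)
        assert {s.scene_id for s in kept} == {"A", "C"}

    def test_all_cooling_subset_is_identity(self, rng):
        slopes = [_slope(-abs(b), sid=f"S{i}")
                  for i, b in enumerate(rng.normal(0, 1, 10))]
        assert subset_cooling(slopes) == slopes

    def test_known_cooling_fraction_preserved(self, rng):
        betas = np.concatenate([-np.abs(rng.normal(1, 0.2, 30)),
                                np.abs(rng.normal(1, 0.2, 10))])
        slopes = [_slope(b, sid=f"S{i}") for i, b in enumerate(betas)]
        assert len(subset_cooling(slopes)) == 30

    def test_no_outlier_variant_identical_without_outliers(self, rng):
        t = rng.uniform(0, 35, 20)
        beta = 0.3 - 0.05 * t + rng.normal(0, 0.05, 20)
        slopes = [_slope(b, var=0.01, t=tt, sid=f"S{i}")
                  for i, (b, tt) in enumerate(zip(beta, t))]
        kept, removed = hampel_filter(slopes)
        if not removed:
            a, b_ = ivw_quadratic(kept), no_outlier_variant(slopes)
            np.testing.assert_allclose(a.coef, b_.coef, rtol=1e-12)

    def test_extreme_outlier_shifts_quadratic_coefficient(self, rng):
        t = rng.uniform(0, 35, 20)
        beta = 0.3 - 0.05 * t + rng.normal(0, 0.05, 20)
        slopes = [_slope(b, var=0.01, t=tt, sid=f"S{i}")
                  for i, (b, tt) in enumerate(zip(beta, t))]
        outlier = _slope(25.0, var=1e-6, t=34.0, sid="SX")
        with_out = no_outlier_variant(slopes + [outlier])
        without = ivw_quadratic(slopes)
        assert with_out.b2 != pytest.approx(without.b2, rel=1e-3)
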