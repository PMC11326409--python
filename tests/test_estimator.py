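"""Recovery of the true birefringence vector from paired measurements."""

import math

import numpy as np
import pytest

from octaxis import (
    ApparentMeasurement,
    Beam,
    EstimatorConfig,
    MeasurementPair,
    MeasurementPairMap,
    TrueBirefringenceVector,
    apparent_from_true,
    axis_from_angles,
    brute_force_oracle,
    choose_branch,
    estimate_map,
    estimate_pixel,
    objective,
    wrap_theta,
    wrap_theta_diff,
)

from conftest import make_pair

OMEGA = 15.0


def recovery_errors(truth, result):
    dth = abs(float(wrap_theta_diff(result.v_hat.theta, truth.theta)))
    dal = abs(result.v_hat.alpha - truth.alpha)
    ddn = abs(result.v_hat.dn / truth.dn - 1.0)
    return dth, dal, ddn


class TestObjective:
    def test_zero_at_generating_truth(self):
        v = axis_from_angles(25.0, 35.0, 5e-4)
        pair = make_pair(25.0, 35.0, 5e-4)
        assert objective(v, pair) < 1e-24

    def test_half_magnitude_trial_residual(self):
        # truth (0, 0, dn): measured vectors are dn [1,0,0] (normal) and
        # dn cos^2 W [cosW, 0, -sinW] (tilted).  A trial at half magnitude
        # along the same axis leaves residuals 0.5 dn and 0.5 dn cos^2 W.
        dn = 6e-4
        w = math.radians(OMEGA)
        pair = make_pair(0.0, 0.0, dn)
        trial = axis_from_angles(0.0, 0.0, 0.5 * dn)
        expected = (0.5 * dn) ** 2 + (0.5 * dn * math.cos(w) ** 2) ** 2
        assert objective(trial, pair) == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_axis_negation(self):
        pair = make_pair(40.0, 20.0, 5e-4)
        v = axis_from_angles(10.0, -15.0, 4e-4)
        v_neg = TrueBirefringenceVector(dn=v.dn, theta=v.theta, alpha=v.alpha,
                                        axis=-v.axis)
        assert objective(v, pair) == pytest.approx(objective(v_neg, pair),
                                                   rel=1e-12)

    def test_same_optimum_in_both_branches(self):
        pair = make_pair(10.0, 30.0, 5e-4)
        v = axis_from_angles(10.0, 30.0, 5e-4)
        assert objective(v, pair, swapped=False) < 1e-24
        assert objective(v, pair, swapped=True) < 1e-24


class TestChooseBranch:
    @pytest.mark.parametrize("theta1, expected", [
        (10.0, "standard"),
        (-10.0, "standard"),
        (80.0, "swapped"),
        (-80.0, "swapped"),
        (45.0, "swapped"),   # boundary belongs to the swapped branch
        (44.999, "standard"),
    ])
    def test_threshold(self, theta1, expected):
        m1 = ApparentMeasurement(5e-4, theta1, Beam.normal())
        assert choose_branch(m1, 45.0) == expected

    def test_undefined_theta_rejected(self):
        m1 = ApparentMeasurement(0.0, 0.0, Beam.normal(), defined=False)
        with pytest.raises(ValueError):
            choose_branch(m1)


class TestEstimatePixel:
    def test_noiseless_recovery(self):
        truth = axis_from_angles(20.0, 40.0, 5e-4)
        r = estimate_pixel(make_pair(20.0, 40.0, 5e-4))
        dth, dal, ddn = recovery_errors(truth, r)
        assert dth < 0.5 and dal < 0.5 and ddn < 0.01
        assert not r.swapped

    def test_swapped_branch_recovery(self):
        truth = axis_from_angles(75.0, -25.0, 5e-4)
        r = estimate_pixel(make_pair(75.0, -25.0, 5e-4))
        assert r.swapped
        dth, dal, ddn = recovery_errors(truth, r)
        assert dth < 0.5 and dal < 0.5 and ddn < 0.01

    def test_inclination_sign_is_distinguished(self):
        r_pos = estimate_pixel(make_pair(0.0, 30.0, 5e-4))
        r_neg = estimate_pixel(make_pair(0.0, -30.0, 5e-4))
        assert r_pos.v_hat.alpha == pytest.approx(30.0, abs=0.5)
        assert r_neg.v_hat.alpha == pytest.approx(-30.0, abs=0.5)

    def test_dark_pixel_is_masked(self):
        pair = MeasurementPair(
            m1=ApparentMeasurement(0.0, 0.0, Beam.normal()),
            m2=ApparentMeasurement(0.0, 0.0, Beam.tilted_y(OMEGA)),
            omega_deg=OMEGA)
        assert estimate_pixel(pair).masked

    def test_branch_continuity_across_swap_boundary(self):
        # recovery error shows no jump where |theta1| crosses 45 deg
        for theta in np.arange(40.0, 50.1, 1.0):
            truth = axis_from_angles(theta, 20.0, 5e-4)
            r = estimate_pixel(make_pair(theta, 20.0, 5e-4))
            dth, dal, ddn = recovery_errors(truth, r)
            assert dth < 0.5 and dal < 0.5 and ddn < 0.01

    def test_coplanar_axis_recovery(self):
        # axis in the plane spanned by the two beams (theta = 0)
        for alpha in (-60.0, -15.0, 7.5, 50.0):
            truth = axis_from_angles(0.0, alpha, 5e-4)
            r = estimate_pixel(make_pair(0.0, alpha, 5e-4))
            dth, dal, ddn = recovery_errors(truth, r)
            assert dth < 0.5 and dal < 0.5 and ddn < 0.01

    def test_paper_zero_initialization_still_converges_from_easy_truths(self):
        cfg = EstimatorConfig(init_strategy="paper_zero", max_iter=5000)
        truth = axis_from_angles(10.0, 20.0, 5e-4)
        r = estimate_pixel(make_pair(10.0, 20.0, 5e-4), cfg)
        dth, dal, ddn = recovery_errors(truth, r)
        assert dth < 1.0 and dal < 1.0 and ddn < 0.05


class TestEstimateMap:
    def _uniform_map(self, theta, alpha, dn, shape=(6, 6)):
        v = axis_from_angles(theta, alpha, dn)
        m1 = apparent_from_true(v, Beam.normal())
        m2 = apparent_from_true(v, Beam.tilted_y(OMEGA))
        full = np.ones(shape)
        return MeasurementPairMap(dn1=m1.dn_app * full, theta1=m1.theta_app * full,
                                  dn2=m2.dn_app * full, theta2=m2.theta_app * full,
                                  omega_deg=OMEGA, mask=np.ones(shape, dtype=bool))

    def test_uniform_map_equals_single_pixel(self):
        maps = self._uniform_map(30.0, 25.0, 5e-4)
        single = estimate_pixel(maps.pixel(0, 0))
        out = estimate_map(maps)
        assert out.mask.all()
        np.testing.assert_allclose(out.theta, single.v_hat.theta, atol=1e-12)
        np.testing.assert_allclose(out.alpha, single.v_hat.alpha, atol=1e-12)
        np.testing.assert_allclose(out.dn, single.v_hat.dn, atol=1e-20)

    def test_mask_propagates(self, rng):
        maps = self._uniform_map(30.0, 25.0, 5e-4, shape=(10, 10))
        drop = rng.random((10, 10)) < 0.1
        maps.mask[drop] = False
        out = estimate_map(maps)
        np.testing.assert_array_equal(out.mask, ~drop)
        assert np.isnan(out.theta[drop]).all()

    def test_two_homogeneous_halves(self):
        top = self._uniform_map(10.0, 20.0, 4e-4, shape=(4, 8))
        bot = self._uniform_map(-50.0, -35.0, 7e-4, shape=(4, 8))
        maps = MeasurementPairMap(
            dn1=np.vstack([top.dn1, bot.dn1]), theta1=np.vstack([top.theta1, bot.theta1]),
            dn2=np.vstack([top.dn2, bot.dn2]), theta2=np.vstack([top.theta2, bot.theta2]),
            omega_deg=OMEGA, mask=np.ones((8, 8), dtype=bool))
        out = estimate_map(maps)
        r_top = estimate_pixel(top.pixel(0, 0))
        r_bot = estimate_pixel(bot.pixel(0, 0))
        np.testing.assert_allclose(out.theta[:4], r_top.v_hat.theta, atol=1e-12)
        np.testing.assert_allclose(out.theta[4:], r_bot.v_hat.theta, atol=1e-12)
        np.testing.assert_allclose(out.alpha[4:], r_bot.v_hat.alpha, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MeasurementPairMap(dn1=np.zeros((4, 4)), theta1=np.zeros((4, 4)),
                               dn2=np.zeros((4, 5)), theta2=np.zeros((4, 5)),
                               omega_deg=OMEGA, mask=np.ones((4, 4), dtype=bool))


class TestBruteForceOracle:
    def test_grid_aligned_truth_recovered_exactly(self):
        pair = make_pair(20.0, 40.0, 5e-4)
        r = brute_force_oracle(pair, grid_step_deg=5.0, dn_grid=[4e-4, 5e-4, 6e-4])
        assert r.v_hat.theta == pytest.approx(20.0, abs=1e-9)
        assert r.v_hat.alpha == pytest.approx(40.0, abs=1e-9)
        assert r.v_hat.dn == pytest.approx(5e-4, rel=1e-12)

    def test_simplex_never_worse_than_grid(self, rng):
        dn_grid = np.linspace(1e-4, 1e-3, 19)
        for _ in range(10):
            truth = axis_from_angles(rng.uniform(-90, 90), rng.uniform(-80, 80),
                                     rng.uniform(2e-4, 8e-4))
            m1 = apparent_from_true(truth, Beam.normal())
            m2 = apparent_from_true(truth, Beam.tilted_y(OMEGA))
            m1n = ApparentMeasurement(
                max(0.0, m1.dn_app * (1 + 0.05 * rng.standard_normal())),
                float(wrap_theta(m1.theta_app + 3.0 * rng.standard_normal())),
                m1.beam)
            m2n = ApparentMeasurement(
                max(0.0, m2.dn_app * (1 + 0.05 * rng.standard_normal())),
                float(wrap_theta(m2.theta_app + 3.0 * rng.standard_normal())),
                m2.beam)
            pair = MeasurementPair(m1=m1n, m2=m2n, omega_deg=OMEGA)
            est = estimate_pixel(pair)
            oracle = brute_force_oracle(pair, 2.0, dn_grid)
            assert est.objective <= oracle.objective * (1 + 1e-9) + 1e-18

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            brute_force_oracle(make_pair(0.0, 0.0, 5e-4), 5.0, dn_grid=[])

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            brute_force_oracle(make_pair(0.0, 0.0, 5e-4), 10.0, dn_grid=[5e-4])


class TestNoiseRobustness:
    def test_median_inclination_error_under_noise(self):
        # wrapped Gaussian orientation noise (3 deg) and 5% relative
        # birefringence noise; regression guard at alpha = 30 deg
        from octaxis import PhantomSpec, simulate_pair_map

        spec = PhantomSpec(shape=(20, 25), theta=20.0, alpha=30.0, dn=5e-4,
                           omega_deg=OMEGA, noise_theta_deg=3.0,
                           noise_dn_rel=0.05, seed=11)
        pair_map, _ = simulate_pair_map(spec)
        out = estimate_map(pair_map)
        err = np.abs(out.alpha[out.mask] - 30.0)
        assert out.mask.sum() == 500
        assert np.median(err) < 5.0


class TestTrueBirefringenceInvariance:
    def test_dn_constant_across_inclinations(self):
        # apparent birefringence falls as cos^2(alpha); the recovered true
        # birefringence must not
        dn = 6.2e-4
        recovered = []
        for alpha in np.arange(-60.0, 60.1, 15.0):
            r = estimate_pixel(make_pair(10.0, alpha, dn))
            recovered.append(r.v_hat.dn)
        recovered = np.array(recovered)
        assert np.std(recovered) / np.mean(recovered) < 0.01
        np.testing.assert_allclose(recovered, dn, rtol=0.01)
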