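"""Estimator battery against independent closed-form / brute-force oracles."""

import numpy as np
import pytest

from mrmediate import (
    InputError,
    InsufficientDataError,
    ivw,
    mode_estimate,
    mr_egger,
    run_estimators,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)

from conftest import make_harmonized


# ---------- independent oracles ----------

def wls_oracle(X, y, w):
    """Weighted least squares by explicit normal equations."""
    Xw = X * w[:, None]
    coef = np.linalg.solve(X.T @ Xw, Xw.T @ y)
    cov = np.linalg.inv(X.T @ Xw)
    return coef, np.sqrt(np.diag(cov))


def weighted_median_oracle(ratio, weight):
    """Cumulative-weight scan with linear interpolation at probability 0.5."""
    order = np.argsort(ratio)
    r = np.array(ratio)[order]
    w = np.array(weight)[order] / np.sum(weight)
    cum = 0.0
    centers = []
    for wi in w:
        centers.append(cum + wi / 2)
        cum += wi
    centers = np.array(centers)
    if 0.5 <= centers[0]:
        return r[0]
    if 0.5 >= centers[-1]:
        return r[-1]
    j = np.searchsorted(centers, 0.5) - 1
    frac = (0.5 - centers[j]) / (centers[j + 1] - centers[j])
    return r[j] + frac * (r[j + 1] - r[j])


def mode_oracle(ratio, weight, bandwidth):
    """Two-stage dense-grid maximization of the weighted kernel density."""
    ratio = np.asarray(ratio, float)
    weight = np.asarray(weight, float) / np.sum(weight)

    def dens(x):
        return np.exp(-0.5 * ((x[:, None] - ratio[None, :]) / bandwidth) ** 2) @ weight

    lo, hi = ratio.min() - 3 * bandwidth, ratio.max() + 3 * bandwidth
    coarse = np.linspace(lo, hi, 100_001)
    x0 = coarse[np.argmax(dens(coarse))]
    step = coarse[1] - coarse[0]
    fine = np.linspace(x0 - 2 * step, x0 + 2 * step, 200_001)
    return float(fine[np.argmax(dens(fine))])


# ---------- tests ----------

class TestWaldRatio:
    def test_hand_evaluated(self):
        est = wald_ratio({"beta_exp": 0.1, "beta_out": 0.02, "se_out": 0.01})
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio({"beta_exp": 0.1, "beta_out": 0.0, "se_out": 0.01})
        assert est.beta == 0.0

    def test_sign_symmetry(self):
        a = wald_ratio({"beta_exp": 0.1, "beta_out": 0.02, "se_out": 0.01})
        b = wald_ratio({"beta_exp": -0.1, "beta_out": 0.02, "se_out": 0.01})
        assert b.beta == -a.beta and b.se == a.se

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(InputError):
            wald_ratio({"beta_exp": 0.0, "beta_out": 0.02, "se_out": 0.01})


class TestIVW:
    def test_two_row_closed_form(self):
        h = make_harmonized(bx=[0.1, 0.2], by=[0.02, 0.05], sy=[0.01, 0.02])
        est = ivw(h, "fixed")
        w = np.array([1e4, 2500.0])
        bx = np.array([0.1, 0.2])
        by = np.array([0.02, 0.05])
        expected = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.beta == pytest.approx(0.225)
        assert est.se == pytest.approx(np.sqrt(1 / np.sum(w * bx**2)), rel=1e-12)

    def test_single_row_matches_wald(self):
        h = make_harmonized(bx=[0.1], by=[0.02], sy=[0.01])
        est = ivw(h)
        wald = wald_ratio({"beta_exp": 0.1, "beta_out": 0.02, "se_out": 0.01})
        assert est.beta == wald.beta and est.se == wald.se

    def test_homogeneous_ratios_collapse_fixed_and_random(self):
        h = make_harmonized(bx=[0.1, 0.2, 0.4], by=[0.03, 0.06, 0.12], sy=[0.01, 0.01, 0.01])
        fixed, random = ivw(h, "fixed"), ivw(h, "random")
        assert fixed.beta == pytest.approx(0.3, rel=1e-12)
        assert random.beta == fixed.beta
        assert random.se == pytest.approx(fixed.se)  # Q = 0 -> multiplier 1

    def test_equals_weighted_mean_of_wald_ratios(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 8)
        by = rng.normal(0.1 * bx, 0.01)
        sy = rng.uniform(0.005, 0.02, 8)
        h = make_harmonized(bx=bx, by=by, sy=sy)
        ratios = by / bx
        w = bx**2 / sy**2
        assert ivw(h, "fixed").beta == pytest.approx(
            np.sum(w * ratios) / np.sum(w), rel=1e-12
        )

    def test_insufficient_data(self):
        h = make_harmonized(bx=[], by=[], sy=[])
        with pytest.raises(InsufficientDataError):
            ivw(h)


class TestMREgger:
    def test_no_pleiotropy_limit(self):
        h = make_harmonized(bx=[0.1, 0.2, 0.4], by=[0.03, 0.06, 0.12], sy=[0.01, 0.02, 0.01])
        est = mr_egger(h)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.3, rel=1e-10)

    def test_three_row_wls_oracle(self):
        bx = np.array([0.1, 0.25, 0.4])
        by = np.array([0.04, 0.05, 0.13])
        sy = np.array([0.01, 0.02, 0.015])
        h = make_harmonized(bx=bx, by=by, sy=sy)
        est = mr_egger(h)
        X = np.column_stack([np.ones(3), bx])
        coef, se_unit = wls_oracle(X, by, 1 / sy**2)
        q = np.sum((by - X @ coef) ** 2 / sy**2)
        mult = max(1.0, np.sqrt(q / (3 - 2)))
        assert est.intercept == pytest.approx(coef[0], rel=1e-10)
        assert est.beta == pytest.approx(coef[1], rel=1e-10)
        assert est.se == pytest.approx(se_unit[1] * mult, rel=1e-10)
        assert est.intercept_se == pytest.approx(se_unit[0] * mult, rel=1e-10)

    def test_constant_shift_moves_intercept_only(self):
        bx = np.array([0.1, 0.25, 0.4, 0.3])
        by = np.array([0.04, 0.05, 0.13, 0.02])
        sy = np.full(4, 0.01)
        base = mr_egger(make_harmonized(bx=bx, by=by, sy=sy))
        shifted = mr_egger(make_harmonized(bx=bx, by=by + 0.05, sy=sy))
        assert shifted.beta == pytest.approx(base.beta, rel=1e-10)
        assert shifted.intercept == pytest.approx(base.intercept + 0.05, rel=1e-10)

    def test_orientation_makes_result_invariant_to_exposure_sign(self):
        bx = np.array([0.1, -0.25, 0.4])
        by = np.array([0.04, -0.05, 0.13])
        sy = np.array([0.01, 0.02, 0.015])
        a = mr_egger(make_harmonized(bx=bx, by=by, sy=sy))
        b = mr_egger(make_harmonized(bx=-bx, by=-by, sy=sy))
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)

    def test_requires_three_rows(self):
        h = make_harmonized(bx=[0.1, 0.2], by=[0.02, 0.05], sy=[0.01, 0.02])
        with pytest.raises(InsufficientDataError):
            mr_egger(h)


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        # equal weights need equal se(ratio): se_out proportional to |bx|
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.03, 0.02])
        sy = np.full(3, 0.01)
        est = weighted_median(make_harmonized(bx=bx, by=by, sy=sy), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2, rel=1e-12)

    def test_interpolation_matches_brute_force_scan(self):
        # ratios {0.1, 0.2, 0.9} with normalized weights {0.5, 0.3, 0.2}
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.2, 0.9])
        sy = 1.0 / np.sqrt(np.array([0.5, 0.3, 0.2]))
        est = weighted_median(make_harmonized(bx=bx, by=by, sy=sy), n_boot=100, seed=0)
        oracle = weighted_median_oracle([0.1, 0.2, 0.9], [0.5, 0.3, 0.2])
        assert oracle == pytest.approx(0.1625, rel=1e-12)  # hand evaluation
        assert est.beta == pytest.approx(oracle, abs=1e-6)

    def test_random_sets_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(3, 9)
            bx = rng.uniform(0.05, 0.4, n)
            by = rng.normal(0.1 * bx, 0.02)
            sy = rng.uniform(0.005, 0.03, n)
            est = weighted_median(make_harmonized(bx=bx, by=by, sy=sy), n_boot=10, seed=0)
            oracle = weighted_median_oracle(by / bx, bx**2 / sy**2)
            assert est.beta == pytest.approx(oracle, abs=1e-6)

    def test_bootstrap_se_reproducible_and_seed_stable(self):
        bx = np.linspace(0.1, 0.4, 10)
        rng = np.random.default_rng(1)
        by = rng.normal(0.2 * bx, 0.02)
        sy = np.full(10, 0.02)
        h = make_harmonized(bx=bx, by=by, sy=sy)
        a = weighted_median(h, n_boot=5000, seed=3)
        b = weighted_median(h, n_boot=5000, seed=3)
        c = weighted_median(h, n_boot=5000, seed=4)
        assert a.se == b.se  # same seed, same stream
        assert c.se == pytest.approx(a.se, rel=0.2)  # Monte-Carlo tolerance


class TestModeEstimators:
    def test_point_mass(self):
        h = make_harmonized(bx=[0.1, 0.2, 0.4], by=[0.03, 0.06, 0.12], sy=[0.01] * 3)
        est = mode_estimate(h, "simple", n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.3)
        assert est.se == 0.0

    @pytest.mark.parametrize("variant", ["simple", "weighted"])
    def test_cluster_argmax_matches_grid_oracle(self, variant):
        bx = np.ones(4)
        by = np.array([0.1, 0.11, 0.12, 0.5])
        sy = np.full(4, 0.05)
        h = make_harmonized(bx=bx, by=by, sy=sy)
        est = mode_estimate(h, variant, n_boot=10, seed=0)
        from mrmediate.estimators import _mode_bandwidth

        ratios = by / bx
        weights = np.ones(4) if variant == "simple" else bx**2 / sy**2
        bw = _mode_bandwidth(ratios, 1.0)
        oracle = mode_oracle(ratios, weights, bw)
        assert abs(oracle - 0.11) < 0.02  # sits in the cluster
        assert est.beta == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_weights_pin_the_estimate(self):
        bx = np.ones(4)
        by = np.array([0.1, 0.3, 0.5, 0.7])
        sy = np.array([1e-6, 1.0, 1.0, 1.0])  # essentially all weight on SNP 1
        est = mode_estimate(make_harmonized(bx=bx, by=by, sy=sy), "weighted",
                            n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.1, abs=1e-4)

    def test_requires_three_rows(self):
        h = make_harmonized(bx=[0.1, 0.2], by=[0.02, 0.05], sy=[0.01, 0.02])
        with pytest.raises(InsufficientDataError):
            mode_estimate(h, "simple")


class TestOddsScale:
    def test_null_effect(self):
        odds = to_odds_scale(0.0, 0.1)
        assert odds["or_"] == 1.0
        assert odds["ci_low"] * odds["ci_high"] == pytest.approx(1.0)

    def test_se_must_be_positive(self):
        with pytest.raises(InputError):
            to_odds_scale(0.1, 0.0)


class TestEquivariance:
    def test_row_order_does_not_change_point_estimates(self):
        rng = np.random.default_rng(9)
        n = 12
        bx = rng.uniform(0.05, 0.4, n)
        by = rng.normal(0.15 * bx, 0.02)
        sy = rng.uniform(0.01, 0.03, n)
        perm = rng.permutation(n)
        h1 = make_harmonized(bx=bx, by=by, sy=sy)
        h2 = make_harmonized(bx=bx[perm], by=by[perm], sy=sy[perm])
        assert ivw(h1).beta == pytest.approx(ivw(h2).beta, rel=1e-12)
        assert mr_egger(h1).beta == pytest.approx(mr_egger(h2).beta, rel=1e-10)
        assert weighted_median(h1, n_boot=5, seed=0).beta == pytest.approx(
            weighted_median(h2, n_boot=5, seed=0).beta, rel=1e-10
        )
        assert mode_estimate(h1, "weighted", n_boot=5, seed=0).beta == pytest.approx(
            mode_estimate(h2, "weighted", n_boot=5, seed=0).beta, abs=1e-8
        )

    def test_agreement_without_pleiotropy(self):
        import mrmediate

        tri = mrmediate.simulate_triple(
            n_snps_instrument=80, n_snps_mediator=0, n_snps_null=0,
            a=0.3, b=1.0, c_direct=0.0, seed=2,
        )
        h = mrmediate.harmonize(tri.exposure, tri.outcome)
        ests = run_estimators(h, n_boot=200, seed=0)
        betas = {e.method: e.beta for e in ests}
        for m, b in betas.items():
            assert b == pytest.approx(0.3, abs=0.05), m
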