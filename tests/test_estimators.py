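"""Tests of the four MR estimators against hand calculations and
independent normal-equation / brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from targetmr.estimators import (
    conmix,
    egger,
    ivw,
    ratio_single,
    weighted_median,
)
from targetmr.exceptions import InsufficientInstrumentsError
from .conftest import make_set, simulated_set


def _wls_normal_equations(bx, by, sy, intercept):
    """Independent oracle: solve the weighted normal equations directly."""
    w = 1.0 / np.asarray(sy) ** 2
    X = np.column_stack([np.ones_like(bx), bx]) if intercept else np.asarray(bx)[:, None]
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * by)
    return np.linalg.solve(A, b)


class TestIVW:
    def test_hand_example_exact(self, collinear_set):
        est = ivw(collinear_set, model="fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-14)
        assert est.se == pytest.approx(np.sqrt(1 / 1400), abs=1e-14)

    def test_single_instrument_degenerates_to_wald_ratio(self):
        iset = make_set([0.2], [0.01], [0.1], [0.01])
        est = ivw(iset)
        assert est.method == "WaldRatio"
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.05)

    def test_homogeneous_random_equals_fixed(self, collinear_set):
        fixed = ivw(collinear_set, model="fixed")
        random = ivw(collinear_set, model="random")
        assert random.se == pytest.approx(fixed.se)  # Q = 0 clamps the scale at 1

    def test_random_se_never_below_fixed(self):
        iset = simulated_set(seed=8, n_variants=30, invalid_fraction=0.3, pleiotropy_sd=0.1)
        assert ivw(iset, "random").se >= ivw(iset, "fixed").se

    @pytest.mark.parametrize("j", [2, 3, 4])
    def test_matches_normal_equation_oracle(self, j):
        rng = np.random.default_rng(j)
        bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
        by = 0.4 * bx + rng.normal(0, 0.02, j)
        sy = rng.uniform(0.005, 0.03, j)
        iset = make_set(bx, np.full(j, 0.01), by, sy)
        (oracle,) = _wls_normal_equations(bx, by, sy, intercept=False)
        assert ivw(iset, "fixed").beta == pytest.approx(oracle, abs=1e-10)

    def test_empty_set_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_set([], [], [], []))


class TestEgger:
    def test_collinear_set_exact(self, collinear_set):
        slope, intercept = egger(collinear_set)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_intercept_shift_identity(self):
        """Adding c to every beta_y (all beta_x > 0, equal weights) shifts
        the intercept by c and leaves the slope unchanged."""
        bx = np.array([0.1, 0.15, 0.25, 0.3])
        by = np.array([0.04, 0.09, 0.11, 0.16])
        sy = np.full(4, 0.01)
        base_slope, base_int = egger(make_set(bx, sy, by, sy))
        c = 0.07
        shift_slope, shift_int = egger(make_set(bx, sy, by + c, sy))
        assert shift_slope.beta == pytest.approx(base_slope.beta, abs=1e-10)
        assert shift_int.beta == pytest.approx(base_int.beta + c, abs=1e-10)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.15, 0.25, -0.3])
        by = np.array([0.04, -0.09, 0.11, -0.16])
        sy = np.full(4, 0.01)
        a = egger(make_set(bx, sy, by, sy))
        b = egger(make_set(-bx, sy, -by, sy))
        assert a[0].beta == pytest.approx(b[0].beta, abs=1e-12)
        assert a[1].beta == pytest.approx(b[1].beta, abs=1e-12)
        assert a[0].se == pytest.approx(b[0].se, abs=1e-12)

    @pytest.mark.parametrize("j", [3, 4])
    def test_matches_normal_equation_oracle(self, j):
        rng = np.random.default_rng(100 + j)
        bx = rng.uniform(0.05, 0.3, j)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.02, j)
        sy = rng.uniform(0.005, 0.03, j)
        iset = make_set(bx, np.full(j, 0.01), by, sy)
        oracle_int, oracle_slope = _wls_normal_equations(bx, by, sy, intercept=True)
        slope, intercept = egger(iset)
        assert slope.beta == pytest.approx(oracle_slope, abs=1e-10)
        assert intercept.beta == pytest.approx(oracle_int, abs=1e-10)

    def test_recovers_directional_pleiotropy(self):
        """With alpha ~ Normal(mu, sd^2) on (essentially) all variants and
        all-positive exposure effects (InSIDE holds), the median intercept
        over replicates is within 2 MC SEs of mu."""
        mu = 0.05
        intercepts = []
        for seed in range(150):
            iset = simulated_set(
                seed=seed,
                n_variants=50,
                invalid_fraction=0.999,
                pleiotropy_mean=mu,
                pleiotropy_sd=0.02,
                random_sign=False,
            )
            intercepts.append(egger(iset)[1].beta)
        intercepts = np.array(intercepts)
        mc_se = 1.2533 * intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(np.median(intercepts) - mu) < 2 * mc_se

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_set([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))


class TestWeightedMedian:
    def test_identical_ratios(self):
        iset = make_set([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.01, 0.02, 0.05])
        est = weighted_median(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_symmetric_ratios_equal_ses(self):
        # ratios 0.4, 0.5, 0.6 with equal ratio SEs -> interpolates to 0.5
        iset = make_set([0.1] * 3, [0.01] * 3, [0.04, 0.05, 0.06], [0.01] * 3)
        est = weighted_median(iset, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-12)

    def test_interpolation_matches_bruteforce(self):
        """Freeze the estimate against a direct evaluation of the
        cumulative-midpoint interpolation formula."""
        ratios = np.array([0.2, 0.45, 0.5, 0.9])
        ses = np.array([0.05, 0.02, 0.04, 0.1])
        iset = make_set(np.ones(4), np.full(4, 0.01), ratios, ses)
        w = ses**-2
        order = np.argsort(ratios)
        r, wn = ratios[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2
        expected = np.interp(0.5, s, r)
        est = weighted_median(iset, n_boot=50, seed=0)
        assert est.beta == pytest.approx(expected, abs=1e-14)

    def test_bootstrap_se_deterministic_given_seed(self):
        iset = simulated_set(seed=3, n_variants=10)
        a = weighted_median(iset, n_boot=200, seed=5)
        b = weighted_median(iset, n_boot=200, seed=5)
        assert a.se == b.se > 0

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_set([0.1], [0.01], [0.05], [0.01]))


class TestConMix:
    def test_identical_ratios_single_atom(self):
        iset = make_set([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.01] * 3)
        with pytest.warns(UserWarning, match="psi"):
            est = conmix(iset)
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.ci_low <= 0.5 <= est.ci_high

    def test_all_valid_classification_matches_density_oracle(self):
        iset = simulated_set(seed=17, n_variants=10, theta=0.3)
        est = conmix(iset)
        # independent check: direct density comparison at the optimum
        psi = est.extras["psi"]
        valid = [
            stats.norm.pdf(r, loc=est.beta, scale=s)
            > stats.norm.pdf(r, loc=0.0, scale=np.sqrt(s**2 + psi**2))
            for r, s in zip(iset.wald_ratios, iset.ratio_ses)
        ]
        assert est.extras["n_valid"] == sum(valid) == 10
        assert set(est.extras["valid_ids"]) == set(iset.variant_ids)

    def test_two_clusters_give_disjoint_region(self):
        # symmetric clusters at +/-0.6, each tight enough that the profile
        # likelihood has twin peaks of equal height
        ratios = np.array([-0.6] * 5 + [0.6] * 5)
        iset = make_set(np.ones(10), np.full(10, 0.01), ratios, np.full(10, 0.03))
        est = conmix(iset, psi=1.0)
        assert est.ci_intervals is not None and len(est.ci_intervals) == 2
        assert est.ci_intervals[0][1] < 0 < est.ci_intervals[1][0]

    def test_profile_likelihood_matches_bruteforce(self):
        """Argmax agrees with a brute-force evaluation on the same grid."""
        iset = simulated_set(seed=23, n_variants=8, theta=0.2)
        est = conmix(iset, psi=0.5, grid_points=501)
        ratios, ses = iset.wald_ratios, iset.ratio_ses
        sd = np.std(ratios, ddof=1)
        grid = np.linspace(ratios.min() - 3 * sd, ratios.max() + 3 * sd, 501)
        ll = []
        for theta in grid:
            total = 0.0
            for r, s in zip(ratios, ses):
                total += np.log(
                    max(
                        stats.norm.pdf(r, theta, s),
                        stats.norm.pdf(r, 0.0, np.sqrt(s**2 + 0.25)),
                    )
                )
            ll.append(total)
        assert est.beta == pytest.approx(grid[int(np.argmax(ll))], abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            conmix(make_set([0.1], [0.01], [0.05], [0.01]))


class TestRatioSingle:
    def test_ci_hand_example(self):
        iset = make_set([1.0], [0.01], [0.5], [0.05])
        est = ratio_single(iset.instruments[0])
        assert est.ci_low == pytest.approx(0.402)
        assert est.ci_high == pytest.approx(0.598)

    def test_zero_outcome_beta(self):
        iset = make_set([0.2], [0.01], [0.0], [0.01])
        assert ratio_single(iset.instruments[0]).beta == 0.0

    def test_small_se_gives_small_p(self):
        iset = make_set([0.2], [0.01], [0.1], [0.001])
        assert ratio_single(iset.instruments[0]).pvalue < 1e-10


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [2.0, 0.5, -3.0])
    def test_all_estimators(self, c):
        """Multiplying exposure betas and SEs by c divides estimates by c."""
        rng = np.random.default_rng(31)
        j = 12
        bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
        sx = np.full(j, 0.005)
        by = 0.4 * bx + rng.normal(0, 0.01, j)
        sy = rng.uniform(0.005, 0.02, j)
        base = make_set(bx, sx, by, sy)
        scaled = make_set(c * bx, abs(c) * sx, by, sy)
        assert ivw(scaled, "fixed").beta == pytest.approx(ivw(base, "fixed").beta / c, rel=1e-10)
        assert egger(scaled)[0].beta == pytest.approx(egger(base)[0].beta / c, rel=1e-10)
        wm_b = weighted_median(base, n_boot=10, seed=0).beta
        wm_s = weighted_median(scaled, n_boot=10, seed=0).beta
        assert wm_s == pytest.approx(wm_b / c, rel=1e-10)
        cm_b = conmix(base, psi=0.3).beta
        cm_s = conmix(scaled, psi=0.3 / abs(c)).beta
        assert cm_s == pytest.approx(cm_b / c, rel=1e-9)
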