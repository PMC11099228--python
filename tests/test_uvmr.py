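import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from axismr.instruments import EstimationError
from axismr.uvmr import METHODS, UVMR, Z95

from conftest import make_harmonized


class TestWald:
    def test_ratio_and_first_order_se(self, harmonized_factory):
        h = harmonized_factory([0.1], [0.05], Gamma_se=[0.02])
        r = UVMR.from_harmonized(h).fit("wald")
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_zero_outcome_effect_gives_null(self, harmonized_factory):
        h = harmonized_factory([0.1], [0.0])
        r = UVMR.from_harmonized(h).fit("wald")
        assert r.beta == 0.0
        assert r.pvalue == 1.0

    def test_signs_cancel(self, harmonized_factory):
        h = harmonized_factory([-0.1], [-0.05])
        assert UVMR.from_harmonized(h).fit("wald").beta == pytest.approx(0.5)

    def test_zero_exposure_effect_errors(self, harmonized_factory):
        h = harmonized_factory([0.0], [0.05])
        with pytest.raises(EstimationError):
            UVMR.from_harmonized(h).fit("wald")


class TestIVW:
    def test_equal_ratios_recovered_exactly(self, harmonized_factory):
        h = harmonized_factory([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        r = UVMR.from_harmonized(h).fit("ivw")
        assert r.beta == pytest.approx(0.5, abs=1e-14)

    def test_fixed_effect_se_closed_form(self, harmonized_factory):
        # sum(gamma^2/se^2) = (0.01+0.04+0.09)/0.01 = 14
        h = harmonized_factory([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        r = UVMR.from_harmonized(h).fit("ivw", model="fixed")
        assert r.se == pytest.approx(1 / np.sqrt(14), rel=1e-12)

    def test_random_effects_se_never_below_fixed(self, rng):
        g = rng.normal(0, 0.1, 30)
        G = 0.3 * g + rng.normal(0, 0.2, 30)  # overdispersed vs se 0.1
        h = make_harmonized(g, G)
        m = UVMR.from_harmonized(h)
        assert m.fit("ivw").se >= m.fit("ivw", model="fixed").se

    def test_single_instrument_directs_to_wald(self, harmonized_factory):
        h = harmonized_factory([0.1], [0.05])
        with pytest.raises(EstimationError, match="wald"):
            UVMR.from_harmonized(h).fit("ivw")

    def test_monte_carlo_recovery_of_true_effect(self, rng):
        """Mean IVW estimate over replicates approaches the true slope."""
        true = 0.3
        est = []
        for _ in range(500):
            g = rng.normal(0, 0.15, 50)
            gse = np.full(50, 0.01)
            Gse = np.full(50, 0.02)
            h = make_harmonized(rng.normal(g, gse), rng.normal(true * g, Gse),
                                gamma_se=gse, Gamma_se=Gse)
            est.append(UVMR.from_harmonized(h).fit("ivw").beta)
        assert abs(np.mean(est) - true) < 0.02


class TestEgger:
    def test_exact_linear_data_recovers_slope_and_intercept(
            self, harmonized_factory):
        g = np.array([0.1, 0.2, 0.3])
        h = harmonized_factory(g, 0.1 + 0.5 * g)
        r = UVMR.from_harmonized(h).fit("egger")
        assert r.beta == pytest.approx(0.5, abs=1e-12)
        assert r.extra["intercept"] == pytest.approx(0.1, abs=1e-12)

    def test_against_weighted_least_squares(self, rng):
        """Slope/intercept match an independent WLS fit (statsmodels)."""
        import statsmodels.api as sm
        g = np.abs(rng.normal(0.2, 0.05, 40))
        Gse = rng.uniform(0.05, 0.15, 40)
        G = 0.05 + 0.4 * g + rng.normal(0, Gse)
        h = make_harmonized(g, G, Gamma_se=Gse)
        r = UVMR.from_harmonized(h).fit("egger")
        wls = sm.WLS(G, sm.add_constant(g), weights=1 / Gse ** 2).fit()
        assert r.beta == pytest.approx(wls.params[1], rel=1e-10)
        assert r.extra["intercept"] == pytest.approx(wls.params[0], rel=1e-10)
        # with sigma-hat > 1 the SEs match WLS exactly; otherwise they are
        # floored at the known-variance (fixed) SE
        sigma = np.sqrt(r.extra["sigma2"])
        expect_se = wls.bse[1] if sigma > 1 else wls.bse[1] / sigma
        assert r.se == pytest.approx(expect_se, rel=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self, rng):
        """Mean fitted intercept over replicates recovers the pleiotropy mean."""
        intercepts = []
        for _ in range(500):
            g = np.abs(rng.normal(0.2, 0.05, 100))
            Gse = np.full(100, 0.05)
            G = 0.05 + 0.2 * g + rng.normal(0, Gse)
            h = make_harmonized(g, G, Gamma_se=Gse)
            intercepts.append(
                UVMR.from_harmonized(h).fit("egger").extra["intercept"])
        assert abs(np.mean(intercepts) - 0.05) < 0.01

    def test_balanced_pleiotropy_intercept_type_one_error(self, rng):
        """Under balanced (InSIDE) pleiotropy the intercept test holds its
        nominal level."""
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            g = np.abs(rng.normal(0.2, 0.05, 60))
            Gse = np.full(60, 0.05)
            pleio = rng.normal(0, 0.05, 60)  # mean-zero, independent of g
            G = 0.3 * g + pleio + rng.normal(0, Gse)
            h = make_harmonized(g, G, Gamma_se=Gse)
            if UVMR.from_harmonized(h).fit("egger").extra["intercept_p"] < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08


def brute_force_weighted_median(ratios, weights):
    """Independent oracle: explicit cumulative-weight interpolation."""
    order = np.argsort(ratios)
    b = np.asarray(ratios)[order]
    w = np.asarray(weights)[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return b[0]
    for j in range(1, len(b)):
        if s[j] >= 0.5:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return b[j - 1] + frac * (b[j] - b[j - 1])
    return b[-1]


class TestWeightedMedian:
    def test_degenerate_distribution(self, harmonized_factory):
        h = harmonized_factory([0.1, 0.2, 0.5], [0.04, 0.08, 0.2])
        r = UVMR.from_harmonized(h).fit("weighted_median", n_boot=50, seed=1)
        assert r.beta == pytest.approx(0.4, abs=1e-12)

    def test_equal_weights_interpolate_middle_ratio(self):
        # 5 ratios 0.1..0.5 with equal ratio variances -> 0.3
        g = np.ones(5)
        G = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        h = make_harmonized(g, G, Gamma_se=np.ones(5))
        r = UVMR.from_harmonized(h).fit("weighted_median", n_boot=50, seed=1)
        assert r.beta == pytest.approx(0.3, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(3, 12))
            g = rng.normal(0, 0.2, k)
            g[np.abs(g) < 0.02] = 0.05
            Gse = rng.uniform(0.01, 0.2, k)
            h = make_harmonized(g, rng.normal(0, 0.2, k), Gamma_se=Gse)
            m = UVMR.from_harmonized(h)
            expected = brute_force_weighted_median(
                m.wald_ratios, 1 / m.ratio_se ** 2)
            got = m.fit("weighted_median", n_boot=50, seed=0).beta
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_robust_to_thirty_percent_invalid_instruments(self, rng):
        """Median stays near truth while IVW is dragged upward."""
        true = 0.3
        med_est, ivw_est = [], []
        for _ in range(500):
            k = 30
            g = rng.normal(0.2, 0.03, k)
            Gse = np.full(k, 0.01)
            G = true * g + rng.normal(0, Gse)
            G[:9] += 0.05  # inflating 30% of ratios
            h = make_harmonized(g, G, Gamma_se=Gse)
            m = UVMR.from_harmonized(h)
            med_est.append(m.fit("weighted_median", n_boot=20, seed=3).beta)
            ivw_est.append(m.fit("ivw").beta)
        assert abs(np.median(med_est) - true) < 0.03
        assert np.median(ivw_est) > true + 0.05

    def test_bootstrap_se_reproducible_for_fixed_seed(self, rng):
        g = rng.normal(0.2, 0.05, 10)
        h = make_harmonized(g, 0.3 * g + rng.normal(0, 0.05, 10))
        m = UVMR.from_harmonized(h)
        a = m.fit("weighted_median", n_boot=200, seed=7)
        b = m.fit("weighted_median", n_boot=200, seed=7)
        assert a.se == b.se


class TestMode:
    def test_degenerate_ratios(self, harmonized_factory):
        h = harmonized_factory([0.1, 0.2, 0.4], [0.025, 0.05, 0.1])
        r = UVMR.from_harmonized(h).fit("weighted_mode", n_boot=20, seed=1)
        assert r.beta == pytest.approx(0.25, abs=1e-12)

    def test_argmax_matches_fine_grid_oracle(self):
        g = np.ones(4)
        G = np.array([0.3, 0.3, 0.3, 0.9])
        h = make_harmonized(g, G, Gamma_se=np.ones(4))
        m = UVMR.from_harmonized(h)
        r = m.fit("simple_mode", n_boot=20, seed=1)
        # independent oracle: evaluate the same KDE on a 10,001-point grid
        ratios = m.wald_ratios
        sd = np.std(ratios, ddof=1)
        mad = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
        hbw = 0.9 * min(s for s in (sd, mad) if s > 0) * 4 ** (-1 / 5)
        grid = np.linspace(-1, 2, 10_001)
        dens = sum(np.exp(-0.5 * ((grid - b) / hbw) ** 2) for b in ratios)
        oracle = grid[np.argmax(dens)]
        assert abs(r.beta - oracle) < 5e-3
        assert abs(r.beta - 0.3) < 0.05

    def test_estimate_moves_continuously_with_bandwidth(self, rng):
        g = np.ones(12)
        G = np.concatenate([rng.normal(0.2, 0.01, 8), rng.normal(0.8, 0.01, 4)])
        h = make_harmonized(g, G, Gamma_se=np.ones(12))
        m = UVMR.from_harmonized(h)
        factors = np.linspace(1.0, 2.0, 11)
        betas = [m.fit("simple_mode", bandwidth_factor=f, n_boot=10, seed=0).beta
                 for f in factors]
        jumps = np.abs(np.diff(betas))
        assert jumps.max() < 0.2  # no discontinuous flip between modes


class TestInvariants:
    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "weighted_mode", "simple_mode"])
    def test_equivariance_under_joint_sign_flip(self, method, rng):
        g = rng.normal(0.2, 0.05, 12)
        G = 0.3 * g + rng.normal(0, 0.05, 12)
        flip = rng.choice([-1.0, 1.0], 12)
        kw = {} if method in ("ivw", "egger") else dict(n_boot=50, seed=5)
        a = UVMR(g, np.full(12, .01), G, np.full(12, .05)).fit(method, **kw)
        b = UVMR(g * flip, np.full(12, .01), G * flip,
                 np.full(12, .05)).fit(method, **kw)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)

    @pytest.mark.parametrize("method", ["ivw", "egger", "weighted_median",
                                        "weighted_mode", "simple_mode"])
    def test_constant_ratio_returned_exactly(self, method):
        g = np.array([0.1, 0.15, 0.2, 0.3])
        c = -0.7
        kw = {} if method in ("ivw", "egger") else dict(n_boot=20, seed=5)
        r = UVMR(g, np.full(4, .01), c * g, np.full(4, .05)).fit(method, **kw)
        assert r.beta == pytest.approx(c, abs=1e-12)

    def test_confidence_interval_and_odds_ratio_identities(self, rng):
        g = rng.normal(0.2, 0.05, 8)
        h = make_harmonized(g, 0.3 * g + rng.normal(0, 0.05, 8))
        r = UVMR.from_harmonized(h).fit("ivw")
        assert r.ci_low == pytest.approx(r.beta - Z95 * r.se, abs=1e-9)
        assert r.ci_high == pytest.approx(r.beta + Z95 * r.se, abs=1e-9)
        assert r.odds_ratio == pytest.approx(np.exp(r.beta), rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_estimates_finite_and_p_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 20))
        g = rng.normal(0, 0.2, k)
        g[np.abs(g) < 1e-3] = 0.1
        h = make_harmonized(g, rng.normal(0, 0.1, k),
                            Gamma_se=rng.uniform(0.01, 0.3, k))
        for method in ("ivw", "egger", "weighted_median"):
            r = UVMR.from_harmonized(h).fit(
                method, **({} if method in ("ivw", "egger")
                           else dict(n_boot=20, seed=0)))
            assert np.isfinite(r.beta) and np.isfinite(r.se)
            assert 0 < r.pvalue <= 1
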