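import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from mrmediate import (
    IVW,
    MREgger,
    ModeEstimator,
    TruthParams,
    WeightedMedian,
    ivw,
    mode_estimators,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrmediate.errors import InsufficientInstrumentsError, UndefinedRatioError
from mrmediate.estimators import _weighted_median_interp
from tests.conftest import make_pair, random_pair, sim_pair_from_truth


class TestWaldRatio:
    def test_hand_values(self):
        est, se = wald_ratio(0.1, 0.0, 0.2, 0.05)
        assert est == pytest.approx(2.0)
        assert se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        est, _ = wald_ratio(0.1, 0.0, 0.0, 0.05)
        assert est == 0.0

    def test_joint_sign_flip_invariance(self):
        est1, se1 = wald_ratio(0.1, 0.01, 0.2, 0.05)
        est2, se2 = wald_ratio(-0.1, 0.01, -0.2, 0.05)
        assert est1 == est2 and se1 == se2

    def test_zero_gamma_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.0, 0.2, 0.05)

    def test_second_order_se_is_larger(self):
        _, se1 = wald_ratio(0.1, 0.02, 0.2, 0.05)
        _, se2 = wald_ratio(0.1, 0.02, 0.2, 0.05, second_order=True)
        assert se2 > se1


class TestIVW:
    def test_two_snp_hand_computation(self):
        # ratios 0.5 (SE 0.1) and 0.3 (SE 0.2): weighted mean 0.46, SE 0.0894
        pair = make_pair([1.0, 1.0], [0.0, 0.0], [0.5, 0.3], [0.1, 0.2])
        est = ivw(pair, variant="fixed")
        assert est.beta == pytest.approx(0.46)
        assert est.se == pytest.approx(1 / np.sqrt(125), rel=1e-10)

    def test_homogeneous_ratios_q_zero_ses_equal(self):
        pair = make_pair([0.1, 0.2, 0.4], [0.0] * 3,
                         [0.05, 0.10, 0.20], [0.01, 0.02, 0.03])
        fe = IVW(variant="fixed").fit(pair)
        mre = IVW(variant="multiplicative_random").fit(pair)
        assert fe.beta_ == pytest.approx(0.5)
        assert fe.q_ == pytest.approx(0.0, abs=1e-20)
        assert fe.se_ == pytest.approx(mre.se_)

    def test_matches_wls_through_origin_oracle(self, rng):
        # IVW == WLS of Gamma on gamma through the origin, weights 1/sigma_y^2
        for _ in range(50):
            pair = random_pair(rng, J=int(rng.integers(5, 40)))
            est = IVW(variant="fixed").fit(pair)
            wls = sm.WLS(pair.Gamma_hat, pair.gamma_hat[:, None],
                         weights=1.0 / pair.sigma_y**2).fit()
            assert est.beta_ == pytest.approx(wls.params[0], abs=1e-10)

    def test_sign_equivariance(self, rng):
        pair = random_pair(rng)
        flipped = make_pair(pair.gamma_hat, pair.sigma_x,
                            -pair.Gamma_hat, pair.sigma_y)
        assert ivw(pair).beta == pytest.approx(-ivw(flipped).beta, abs=1e-14)

    def test_fewer_than_two_snps_rejected(self):
        pair = make_pair([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(pair)

    def test_sklearn_params_round_trip(self):
        est = IVW(variant="fixed")
        assert est.get_params() == {"variant": "fixed"}
        est.set_params(variant="multiplicative_random")
        assert est.variant == "multiplicative_random"


class TestEgger:
    def test_exact_line_recovered(self):
        gamma = np.array([0.05, 0.10, 0.15, 0.22, 0.30])
        Gamma = 0.1 + 0.5 * gamma
        pair = make_pair(gamma, np.zeros(5), Gamma, np.full(5, 0.01))
        fit = MREgger().fit(pair)
        assert fit.intercept_ == pytest.approx(0.1, abs=1e-10)
        assert fit.beta_ == pytest.approx(0.5, abs=1e-10)

    def test_balanced_pleiotropy_intercept_calibrated(self):
        # intercept within +-2 SE of 0 in >= 90% of 200 clean runs
        hits = 0
        for seed in range(200):
            t = TruthParams(seed=seed, n_snps=50, n_snps_mediator=5,
                            pleio_fraction=0.3, pleio_mean=0.0,
                            pleio_sd=0.002, n_out=330_690)
            pair = sim_pair_from_truth(t, "exposure->outcome")
            fit = MREgger().fit(pair)
            hits += abs(fit.intercept_) < 2 * fit.intercept_se_
        assert hits >= 180

    def test_zero_intercept_constraint_is_ivw(self, rng):
        # constraining the intercept to zero with the same weights == IVW fixed
        pair = random_pair(rng)
        wls = sm.WLS(pair.Gamma_hat, pair.gamma_hat[:, None],
                     weights=1.0 / pair.sigma_y**2).fit()
        assert ivw(pair, variant="fixed").beta == pytest.approx(
            wls.params[0], abs=1e-10)

    def test_orientation_makes_estimate_invariant_to_allele_coding(self, rng):
        # re-coding any SNP's effect allele (joint sign flip) leaves Egger alone
        pair = random_pair(rng, J=20)
        flip = rng.choice([1.0, -1.0], size=20)
        recoded = make_pair(pair.gamma_hat * flip, pair.sigma_x,
                            pair.Gamma_hat * flip, pair.sigma_y)
        a, b = MREgger().fit(pair), MREgger().fit(recoded)
        assert a.beta_ == pytest.approx(b.beta_, abs=1e-12)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-12)

    def test_needs_three_snps(self):
        pair = make_pair([0.1, 0.2], [0, 0], [0.1, 0.2], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(pair)


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        pair = make_pair(np.ones(5), np.zeros(5),
                         np.array([1.0, 2, 3, 4, 5]), np.ones(5))
        est = weighted_median(pair, n_boot=50, seed=0)
        assert est.beta == pytest.approx(3.0)

    def test_matches_brute_force_interpolation_oracle(self, rng):
        def brute(ratios, weights):
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            s = np.cumsum(w) - w / 2
            if 0.5 <= s[0]:
                return r[0]
            for i in range(1, len(r)):
                if s[i] >= 0.5:
                    frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
                    return r[i - 1] + frac * (r[i] - r[i - 1])
            return r[-1]

        for _ in range(50):
            n = int(rng.integers(2, 30))
            ratios = rng.normal(size=n)
            weights = rng.uniform(0.1, 5.0, size=n)
            assert _weighted_median_interp(ratios, weights) == pytest.approx(
                brute(ratios, weights), abs=1e-12)

    def test_majority_valid_robustness(self):
        # 40% of SNPs share a large pleiotropic offset: the weighted median
        # stays near truth (valid instruments hold >50% of the weight) while
        # IVW is dragged away
        rng = np.random.default_rng(99)
        J, beta = 50, 0.3
        gamma = np.sort(rng.uniform(0.1, 0.3, J))
        sy = np.full(J, 0.01)
        Gamma = beta * gamma + rng.normal(0, 0.01, J)
        Gamma[:20] += 0.15  # offset on the 40% lowest-weight SNPs
        pair = make_pair(gamma, np.zeros(J), Gamma, sy)
        wm = weighted_median(pair, n_boot=500, seed=1)
        iv = ivw(pair)
        assert abs(wm.beta - beta) < 2 * wm.se
        assert abs(iv.beta - beta) > abs(wm.beta - beta)

    def test_bootstrap_seed_reproducible(self, rng):
        pair = random_pair(rng)
        a = weighted_median(pair, n_boot=100, seed=5)
        b = weighted_median(pair, n_boot=100, seed=5)
        assert a.se == b.se


class TestModes:
    def test_dominant_cluster(self):
        pair = make_pair(np.ones(4), np.zeros(4),
                         np.array([2.0, 2, 2, 9]), np.ones(4))
        est = ModeEstimator(weighted=False, n_boot=50, seed=0).fit(pair)
        h = 0.9 * min(np.std([2, 2, 2, 9], ddof=1),
                      np.median(np.abs(np.array([2, 2, 2, 9]) - 2)) / 0.6745
                      or np.inf) * 4 ** (-0.2)
        grid_step = (7 + 6 * h) / 511
        assert abs(est.beta_ - 2.0) <= grid_step

    def test_phi_never_leaves_ratio_range(self, rng):
        pair = random_pair(rng, J=15)
        ratios = pair.Gamma_hat / pair.gamma_hat
        for phi in (0.5, 1.0, 2.0):
            est = ModeEstimator(weighted=False, phi=phi, n_boot=10, seed=0
                                ).fit(pair)
            assert ratios.min() <= est.beta_ <= ratios.max()

    def test_simple_equals_weighted_under_equal_weights(self):
        # equal ratio SEs make the two mode densities identical
        gamma = np.ones(6)
        Gamma = np.array([0.2, 0.25, 0.3, 0.3, 0.35, 0.9])
        pair = make_pair(gamma, np.zeros(6), Gamma, np.ones(6))
        simple, wmode = mode_estimators(pair, n_boot=10, seed=0)
        assert simple.beta == pytest.approx(wmode.beta)

    def test_homogeneous_ratios_return_common_value(self):
        pair = make_pair([0.1, 0.2, 0.4], [0.0] * 3,
                         [0.05, 0.10, 0.20], [0.01, 0.02, 0.03])
        simple, wmode = mode_estimators(pair, n_boot=20, seed=0)
        wm = weighted_median(pair, n_boot=20, seed=0)
        assert simple.beta == pytest.approx(0.5)
        assert wmode.beta == pytest.approx(0.5)
        assert wm.beta == pytest.approx(0.5)


class TestOddsRatio:
    def test_printed_total_effect_reproduces_or(self):
        or_value, _, _ = to_odds_ratio(-0.966, 0.2)
        assert round(or_value, 3) == 0.381

    def test_null_beta(self):
        or_value, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_value == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric on log scale

    def test_hand_ci(self):
        _, lo, hi = to_odds_ratio(0.2, 0.1)
        assert lo == pytest.approx(np.exp(0.2 - 1.959964 * 0.1))
        assert hi == pytest.approx(np.exp(0.2 + 1.959964 * 0.1))

    @given(beta=st.floats(-3, 3), se=st.floats(0.001, 2))
    def test_ci_brackets_or(self, beta, se):
        or_value, lo, hi = to_odds_ratio(beta, se)
        assert lo <= or_value <= hi
        assert or_value == pytest.approx(np.exp(beta))


class TestParameterRecovery:
    def test_all_estimators_within_two_se_on_clean_data(self):
        # clean simulations with strong instruments (the regime where the
        # no-measurement-error assumption on gamma_hat holds): each
        # estimator covers truth in >= 90% of runs
        methods = {"ivw": 0, "egger": 0, "weighted_median": 0}
        n_rep = 60
        for seed in range(n_rep):
            t = TruthParams(seed=seed, n_snps=150, n_snps_mediator=5,
                            n_exp=300_000, n_med=300_000,
                            f_reference_n=7738)
            pair = sim_pair_from_truth(t, "exposure->outcome")
            iv = ivw(pair)
            eg = mr_egger(pair)
            wm = weighted_median(pair, n_boot=200, seed=seed)
            methods["ivw"] += abs(iv.beta - t.beta_total) < 2 * iv.se
            methods["egger"] += abs(eg.beta - t.beta_total) < 2 * eg.se
            methods["weighted_median"] += abs(wm.beta - t.beta_total) < 2 * wm.se
        for name, hits in methods.items():
            assert hits / n_rep >= 0.90, name
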