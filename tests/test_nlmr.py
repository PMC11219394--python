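"""Stratified-MR orchestration: per-stratum estimation, Rubin's-rules
pooling, Cochran's Q, the trend test and the constant-genetic-effect
check."""

import numpy as np
import pytest

import stratmr
from stratmr import (
    MREstimate,
    StratumEstimateSet,
    StratumSummary,
    cochran_q,
    constant_genetic_effect_check,
    flag_impossibility,
    pool_replicates,
    stratified_mr,
    trend_test,
)


def _make_set(betas, ses, means=None, first=None, overall=None, family="continuous"):
    J = len(betas)
    means = means if means is not None else list(range(J))
    estimates = [MREstimate(beta=b, se=s, n=100, family=family)
                 for b, s in zip(betas, ses)]
    fs = first or [MREstimate(beta=1.0, se=0.1, n=100) for _ in range(J)]
    summaries = [
        StratumSummary(stratum=j + 1, n=100, mean_exposure=float(means[j]),
                       min_exposure=float(means[j]) - 1,
                       max_exposure=float(means[j]) + 1, mean_instrument=0.0)
        for j in range(J)
    ]
    return StratumEstimateSet(
        method="residual", n_strata=J, outcome="y", family=family,
        estimates=estimates, first_stage=fs, summaries=summaries,
        overall=overall or MREstimate(beta=float(np.mean(betas)), se=0.5, n=100),
    )


class TestStratifiedMR:
    def test_single_stratum_equals_overall(self, small_cohort):
        a = stratmr.residual_strata(small_cohort, 1)
        ss = stratified_mr(small_cohort, a, "outcome_continuous", "continuous")
        assert ss.estimates[0].beta == pytest.approx(ss.overall.beta, abs=1e-12)
        assert ss.estimates[0].se == pytest.approx(ss.overall.se, rel=1e-10)

    def test_homogeneous_effect_recovered_in_every_stratum(self):
        cfg = stratmr.null_scenario(n=50_000, seed=17, causal_effect_continuous=0.5)
        coh = stratmr.simulate_cohort(cfg)
        a = stratmr.doubly_ranked_strata(coh, 5)
        ss = stratified_mr(coh, a, "outcome_continuous", "continuous")
        for e in ss.estimates:
            assert e.beta == pytest.approx(0.5, abs=3 * e.se)

    def test_stratum_failure_is_annotated_not_fatal(self):
        cfg = stratmr.null_scenario(n=2_000, seed=18)
        coh = stratmr.simulate_cohort(cfg)
        # an outcome that is all-zero in stratum 1 but mixed overall
        a = stratmr.doubly_ranked_strata(coh, 4)
        yb = np.ones(len(coh), dtype=int)
        ids_1 = set(a.stratum_ids(1))
        yb[coh["id"].isin(ids_1)] = 0
        # make the remaining strata two-class
        coh = coh.assign(outcome_binary=yb)
        rng = np.random.default_rng(0)
        flip = rng.random(len(coh)) < 0.3
        coh.loc[flip & ~coh["id"].isin(ids_1), "outcome_binary"] = 0
        ss = stratified_mr(coh, a, "outcome_binary", "binary")
        assert ss.estimates[0] is None
        assert 1 in ss.errors
        assert all(e is not None for e in ss.estimates[1:])

    def test_unknown_family_rejected(self, small_cohort):
        a = stratmr.residual_strata(small_cohort, 2)
        with pytest.raises(ValueError, match="family"):
            stratified_mr(small_cohort, a, "outcome_continuous", "poisson")


class TestPoolReplicates:
    def test_hand_computed_rubins_rules(self):
        """betas {1.0, 1.2, 1.4} with variances 0.04 pool to beta 1.2,
        B = 0.04, T = 0.04 + (4/3) * 0.04."""
        sets = [_make_set([b], [0.2]) for b in (1.0, 1.2, 1.4)]
        pooled = pool_replicates(sets)
        assert pooled.m == 3
        assert pooled.estimates[0].beta == pytest.approx(1.2)
        assert pooled.within_var[0] == pytest.approx(0.04)
        assert pooled.between_var[0] == pytest.approx(0.04)
        assert pooled.estimates[0].se**2 == pytest.approx(0.04 + (4 / 3) * 0.04)

    def test_identical_replicates_have_zero_between_variance(self):
        sets = [_make_set([0.7, 0.9], [0.1, 0.2]) for _ in range(5)]
        pooled = pool_replicates(sets)
        np.testing.assert_allclose(pooled.between_var, 0.0, atol=1e-15)
        np.testing.assert_allclose(pooled.betas(), [0.7, 0.9])
        np.testing.assert_allclose(pooled.ses(), [0.1, 0.2])

    def test_single_replicate_pooled_variance_is_within_variance(self):
        pooled = pool_replicates([_make_set([0.7], [0.1])])
        assert pooled.m == 1
        assert pooled.estimates[0].se == pytest.approx(0.1)
        assert pooled.between_var[0] == 0.0

    def test_pooling_never_decreases_variance(self):
        rng = np.random.default_rng(8)
        sets = [_make_set(rng.normal(size=3), rng.uniform(0.1, 0.3, 3))
                for _ in range(6)]
        pooled = pool_replicates(sets)
        assert (pooled.ses() ** 2 >= pooled.within_var - 1e-15).all()

    def test_mismatched_strata_counts_raise(self):
        with pytest.raises(ValueError, match="number of strata"):
            pool_replicates([_make_set([1.0], [0.1]), _make_set([1.0, 2.0], [0.1, 0.1])])


class TestCochranQ:
    def test_identical_betas_give_zero_q(self):
        res = cochran_q(_make_set([1.0, 1.0, 1.0], [0.2, 0.3, 0.4]))
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.p_Q == pytest.approx(1.0)
        assert res.df == 2

    def test_two_group_closed_form(self):
        """Q = (1 - 2)^2 / (0.25 + 0.25) = 2 for betas 1, 2 with se 0.5."""
        res = cochran_q(_make_set([1.0, 2.0], [0.5, 0.5]))
        assert res.Q == pytest.approx(2.0)
        assert res.df == 1

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cochran_q(_make_set([1.0, 2.0], [0.0, 0.5]))

    def test_chi_square_calibration(self):
        """Homogeneous simulation: Q rejects at ~5% over many draws."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            ses = rng.uniform(0.1, 0.3, 5)
            betas = rng.normal(0.5, ses)
            if cochran_q(_make_set(list(betas), list(ses))).p_Q < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07


class TestTrendTest:
    def test_exact_linear_trend_recovered(self):
        means = [1.0, 2.0, 3.0, 4.0]
        betas = [0.5 + 0.3 * m for m in means]
        res = trend_test(_make_set(betas, [0.1] * 4, means=means))
        assert res.trend_slope == pytest.approx(0.3, abs=1e-12)
        assert res.p_trend < 1e-6

    def test_weighted_arithmetic_oracle(self):
        """Weights {4, 1, 4} (se 0.5, 1, 0.5) with hand-chosen points."""
        means = [0.0, 1.0, 2.0]
        betas = [1.0, 3.0, 2.0]
        w = np.array([4.0, 1.0, 4.0])
        x, y = np.array(means), np.array(betas)
        xb = (w * x).sum() / w.sum()
        yb = (w * y).sum() / w.sum()
        slope = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        res = trend_test(_make_set(betas, [0.5, 1.0, 0.5], means=means))
        assert res.trend_slope == pytest.approx(slope, abs=1e-12)

    def test_null_calibration(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(500):
            ses = rng.uniform(0.1, 0.3, 5)
            betas = rng.normal(0.0, ses)
            pvals.append(trend_test(_make_set(list(betas), list(ses),
                                              means=list(range(5)))).p_trend)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_means_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            trend_test(_make_set([1.0, 2.0, 3.0], [0.1] * 3, means=[1.0, 1.0, 1.0]))

    def test_too_few_strata_rejected(self):
        with pytest.raises(ValueError, match="3"):
            trend_test(_make_set([1.0, 2.0], [0.1, 0.1]))


class TestConstantGeneticEffectCheck:
    def test_constant_alpha_is_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(400):
            ses = rng.uniform(0.05, 0.1, 5)
            fs = [MREstimate(beta=float(rng.normal(1.0, s)), se=float(s), n=100)
                  for s in ses]
            res = constant_genetic_effect_check(
                _make_set([0.0] * 5, [0.1] * 5, first=fs)
            )
            rejections += res.p_Q < 0.05
        assert 0.02 <= rejections / 400 <= 0.08

    def test_varying_alpha_detected(self):
        """A doubled top-stratum instrument-exposure slope is flagged."""
        cfg = stratmr.null_scenario(n=100_000, seed=12,
                                    genetic_effect_mode="exposure_varying",
                                    genetic_effect_top=2.0)
        coh = stratmr.simulate_cohort(cfg)
        a = stratmr.doubly_ranked_strata(coh, 10)
        ss = stratified_mr(coh, a, "age", "continuous")
        assert constant_genetic_effect_check(ss).p_Q < 0.05

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            constant_genetic_effect_check(_make_set([1.0], [0.1]))


class TestImpossibilityFlag:
    def test_flags_overall_ci_excluding_common_direction(self):
        overall = MREstimate(beta=0.0, se=0.01, n=1000)
        s = _make_set([0.5, 0.6, 0.7], [0.1] * 3, overall=overall)
        with pytest.warns(UserWarning, match="causal interpretation"):
            assert flag_impossibility(s)

    def test_consistent_estimates_not_flagged(self):
        overall = MREstimate(beta=0.6, se=0.1, n=1000)
        s = _make_set([0.5, 0.6, 0.7], [0.1] * 3, overall=overall)
        assert not flag_impossibility(s)
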