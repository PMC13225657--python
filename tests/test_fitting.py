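"""Estimation: IG fits by three routes, share/shift fits, permutation tests."""

import itertools

import numpy as np
import pytest

from relayrt import (
    BinnedData,
    IGParams,
    QuantileSet,
    RelaySpec,
    StagePartition,
    corr_perm_test,
    fit_ig_moments,
    fit_ig_qmpe,
    fit_ig_to_quantiles,
    fit_rt_share,
    fit_shift,
    ig_quantile,
    ig_sample,
    multistage_relay_cdf,
    race_cdf,
    relay_cdf,
    relay_simulate,
    se_to_sd,
    shifted_race_cdf,
    sign_flip_test,
)
from relayrt.fitting import qmpe_nll
from relayrt.race import default_grid
from relayrt.metrics import TEN_QUANTILES
from .conftest import MILLER1982, OTTO_SOA


class TestQuantileFit:
    def test_recovers_exact_generating_parameters(self):
        p = IGParams(400, 8000)
        probs = (np.arange(10) + 0.5) / 10
        q = QuantileSet(probs, ig_quantile(probs, p))
        fit = fit_ig_to_quantiles(q)
        assert fit.params.mu == pytest.approx(400, rel=1e-3)
        assert fit.params.lam == pytest.approx(8000, rel=1e-3)

    def test_local_optimality(self):
        p = IGParams(399, 3272)
        probs = (np.arange(10) + 0.5) / 10
        q = QuantileSet(probs, ig_quantile(probs, p))
        fit = fit_ig_to_quantiles(q)

        def rmse(cand):
            from relayrt import ig_cdf

            return float(np.sqrt(np.mean((ig_cdf(q.rts, cand) - q.probs) ** 2)))

        rng = np.random.default_rng(0)
        for _ in range(100):
            cand = IGParams(
                fit.params.mu * rng.uniform(0.8, 1.25), fit.params.lam * rng.uniform(0.5, 2.0)
            )
            assert fit.objective <= rmse(cand) + 1e-12

    def test_two_points_underdetermined(self):
        with pytest.raises(ValueError):
            fit_ig_to_quantiles(QuantileSet(np.array([0.3, 0.7]), np.array([300.0, 400.0])))


class TestMomentsFit:
    def test_table_row_inversion(self):
        p = fit_ig_moments(231, 56.0)
        assert p.lam == pytest.approx(3931, rel=0.005)

    def test_se_conversion(self):
        assert se_to_sd(2.8, 400) == pytest.approx(56.0)

    def test_roundtrip_with_moments(self):
        from relayrt import ig_moments

        m, s = ig_moments(fit_ig_moments(350.0, 80.0))
        assert (m, s) == (pytest.approx(350.0), pytest.approx(80.0))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fit_ig_moments(-1, 10)
        with pytest.raises(ValueError):
            se_to_sd(0, 100)


class TestQmpe:
    def test_parameter_recovery(self):
        p = IGParams(376, 8619)
        rts = ig_sample(p, 2000, 123)
        fit = fit_ig_qmpe(rts)
        assert fit.params.mu == pytest.approx(p.mu, rel=0.05)
        assert fit.params.lam == pytest.approx(p.lam, rel=0.15)

    def test_nll_prefers_truth_over_distorted_mean(self):
        p = IGParams(376, 8619)
        binned = BinnedData.from_sample(ig_sample(p, 5000, 7))
        assert qmpe_nll(p, binned) < qmpe_nll(IGParams(p.mu * 1.5, p.lam), binned)

    def test_minimum_trial_count(self):
        with pytest.raises(ValueError):
            fit_ig_qmpe(np.full(10, 300.0))

    def test_binned_data_counts(self):
        rts = np.arange(1.0, 101.0)
        b = BinnedData.from_sample(rts)
        assert b.counts.sum() == 100
        assert len(b.counts) == len(b.edges) + 1


class TestShareFit:
    def test_noiseless_quantile_recovery(self):
        truth = relay_cdf(RelaySpec.two_stage(MILLER1982, 0.25))
        q = QuantileSet(TEN_QUANTILES, truth.quantile(TEN_QUANTILES))
        fit = fit_rt_share(MILLER1982, q, objective="cdf_rmse")
        assert fit.params == pytest.approx(0.25, abs=0.01)

    def test_race_target_hits_lower_boundary(self):
        race = multistage_relay_cdf(
            MILLER1982, StagePartition((1.0,)), default_grid([MILLER1982.aud, MILLER1982.vis])
        )
        q = QuantileSet(TEN_QUANTILES, race.quantile(TEN_QUANTILES))
        fit = fit_rt_share(MILLER1982, q, objective="cdf_rmse")
        assert fit.params < 0.02

    def test_joint_nll_recovery_across_soas(self):
        soas = [-60.0, -30.0, 0.0, 30.0, 60.0]
        rng = np.random.default_rng(11)
        binned = [
            BinnedData.from_sample(
                relay_simulate(RelaySpec.two_stage(OTTO_SOA, 0.135, s), 1600, rng)
            )
            for s in soas
        ]
        fit = fit_rt_share(OTTO_SOA, binned, objective="qmpe_nll_joint", soas=soas)
        assert fit.params == pytest.approx(0.135, abs=0.03)

    def test_rse_rmse_recovery(self):
        from relayrt import rse_mean

        soas = [-100.0, -50.0, 0.0, 50.0, 100.0]
        emp = [
            rse_mean(
                relay_cdf(RelaySpec.two_stage(OTTO_SOA, 0.135, s)),
                OTTO_SOA.aud.mu,
                OTTO_SOA.vis.mu,
                s,
            )
            for s in soas
        ]
        fit = fit_rt_share(OTTO_SOA, emp, objective="rse_rmse", soas=soas)
        assert fit.params == pytest.approx(0.135, abs=0.01)

    def test_unisensory_parameters_never_mutated(self):
        # the fixed-unisensory protocol: fitting must not touch the pair
        before = (MILLER1982.aud, MILLER1982.vis)
        truth = relay_cdf(RelaySpec.two_stage(MILLER1982, 0.2))
        q = QuantileSet(TEN_QUANTILES, truth.quantile(TEN_QUANTILES))
        fit_rt_share(MILLER1982, q, objective="cdf_rmse")
        assert (MILLER1982.aud, MILLER1982.vis) == before

    def test_unknown_objective(self):
        with pytest.raises(ValueError):
            fit_rt_share(MILLER1982, None, objective="nope")


class TestShiftFit:
    def test_noiseless_recovery(self):
        grid = default_grid([MILLER1982.aud, MILLER1982.vis])
        target = shifted_race_cdf(MILLER1982, 20.0, grid)
        q = QuantileSet(TEN_QUANTILES, target.quantile(TEN_QUANTILES))
        fit = fit_shift(MILLER1982, q)
        assert fit.params == pytest.approx(20.0, abs=0.5)

    def test_race_target_gives_zero_shift(self):
        grid = default_grid([MILLER1982.aud, MILLER1982.vis])
        target = shifted_race_cdf(MILLER1982, 0.0, grid)
        q = QuantileSet(TEN_QUANTILES, target.quantile(TEN_QUANTILES))
        assert abs(fit_shift(MILLER1982, q).params) < 0.5

    def test_upper_bound_clip_flagged(self):
        grid = default_grid([MILLER1982.aud, MILLER1982.vis])
        # a target whose generating shift (520 ms) exceeds the cap: only the
        # slow tail stays at positive times, and the fit pins delta at 500
        base = shifted_race_cdf(MILLER1982, 0.0, grid)
        probs = np.array([0.99, 0.995, 0.999])
        fast = QuantileSet(probs, base.quantile(probs) - 520.0)
        assert np.all(fast.rts > 0)
        fit = fit_shift(MILLER1982, fast)
        assert fit.params <= 500.0
        assert fit.info.get("at_upper_bound", False)


class TestSignFlip:
    def test_all_zero_values(self):
        assert sign_flip_test(np.zeros(6), rng=0) == pytest.approx(1.0, abs=0.01)

    def test_matches_exhaustive_enumeration(self):
        values = np.array([0.8, 1.1, 0.6, 1.4, 0.9, 1.2, 0.7, 1.0, 1.3, 0.5])
        obs = abs(values.mean())
        count = sum(
            abs(np.mean(np.array(signs) * values)) >= obs - 1e-12
            for signs in itertools.product([-1, 1], repeat=10)
        )
        exact = count / 2**10
        assert sign_flip_test(values, rng=1) == pytest.approx(exact, abs=0.002)

    def test_reproducible_and_validated(self):
        v = np.array([0.1, -0.2, 0.3])
        assert sign_flip_test(v, rng=5) == sign_flip_test(v, rng=5)
        with pytest.raises(ValueError):
            sign_flip_test(v, n_iter=10)
        with pytest.raises(ValueError):
            sign_flip_test(np.array([1.0]))


class TestCorrPerm:
    def test_perfect_linear_association(self):
        x = np.arange(6.0)
        r, p = corr_perm_test(x, 2 * x + 1, n_iter=500, rng=0)
        assert r == pytest.approx(1.0)
        # with n = 6 no permutation p can undercut 1/720
        assert p >= 1 / 720

    def test_null_calibration(self):
        rng = np.random.default_rng(3)
        big = 0
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p = corr_perm_test(x, y, n_iter=2000, rng=rng)
            big += p > 0.05
        assert big >= 18  # ~90% of null runs should be non-significant

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            corr_perm_test(np.ones(5), np.arange(5.0))
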