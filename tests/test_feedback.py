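"""Lagged-covariance estimator, stepwise AIC selection, permutation bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sgefa import (
    SynthConfig,
    assess_feedback,
    backward_stepwise,
    bootstrap_significance,
    estimate_response,
    gen_fire_series,
    gen_forcings,
    lagged_covariance,
    max_response_season,
    robustness_count,
    seasonal_feedback_cycle,
    spatial_response_map,
)
from sgefa.feedback import FeedbackEstimate, aic_score
from sgefa.preprocess import PooledSamples

from .conftest import make_field


def pooled_from(f, o_t, o_lag, tau=1):
    f = np.asarray(f, float)
    o_t = np.atleast_2d(np.asarray(o_t, float).T).T
    o_lag = np.atleast_2d(np.asarray(o_lag, float).T).T
    idx = pd.period_range("2000-01", periods=len(f), freq="M")
    return PooledSamples(f=f, o_t=o_t, o_lag=o_lag, times=idx,
                         n_dropped=0, tau=tau, season=None)


def loop_covariances(f, o_t, o_lag):
    """Explicit loop-sum oracle for the lagged covariances (denominator n-1)."""
    n, k = o_t.shape
    fm = sum(f) / n
    otm = [sum(o_t[:, j]) / n for j in range(k)]
    olm = [sum(o_lag[:, j]) / n for j in range(k)]
    c_fo = np.zeros(k)
    c_oo = np.zeros((k, k))
    for j in range(k):
        c_fo[j] = sum((f[t] - fm) * (o_lag[t, j] - olm[j]) for t in range(n)) / (n - 1)
        for i in range(k):
            c_oo[i, j] = sum(
                (o_t[t, i] - otm[i]) * (o_lag[t, j] - olm[j]) for t in range(n)
            ) / (n - 1)
    return c_fo, c_oo


class TestLaggedCovariance:
    def test_hand_series_matches_loop_oracle(self):
        o = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 1.0])
        f = 2.0 * o
        p = pooled_from(f[1:], o[1:], o[:-1])
        c_fo, c_oo = lagged_covariance(p)
        c_fo_o, c_oo_o = loop_covariances(p.f, p.o_t, p.o_lag)
        assert np.allclose(c_fo, c_fo_o, atol=1e-12)
        assert np.allclose(c_oo, c_oo_o, atol=1e-12)
        assert np.allclose(c_fo, 2.0 * c_oo[0], atol=1e-12)

    def test_tau_zero_identity(self):
        rng = np.random.default_rng(0)
        o = rng.standard_normal(50)
        p = pooled_from(o, o, o, tau=0)
        c_fo, c_oo = lagged_covariance(p)
        assert c_fo[0] == pytest.approx(np.var(o, ddof=1))
        assert c_oo[0, 0] == pytest.approx(np.var(o, ddof=1))

    def test_independent_noise_covariances_vanish(self):
        rng = np.random.default_rng(1)
        n = 5000
        f = rng.standard_normal(n)
        o = rng.standard_normal((n, 3))
        p = pooled_from(f, o, np.roll(o, 1, axis=0))
        c_fo, _ = lagged_covariance(p)
        assert np.abs(c_fo).max() < 3 / np.sqrt(n)


class TestEstimateResponse:
    def test_exact_recovery_without_noise(self):
        cfg = SynthConfig(n_forcings=1, n_years=4, ar1_coeffs=[0.7],
                          forcing_corr=np.eye(1), true_response=[2.0],
                          fire_noise_sd=0.0, seed=2,
                          seasonal_cycle={"fire": np.zeros(12)},
                          trend_slope={"fire": 0.0})
        o = gen_forcings(cfg)
        fire, _ = gen_fire_series(o, cfg)
        ov = o.to_numpy()
        p = pooled_from(fire.values[1:], ov[1:], ov[:-1])
        assert estimate_response(p)[0] == pytest.approx(2.0, abs=1e-10)

    def test_matches_loop_oracle_random_instance(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(40)
        o_t = rng.standard_normal((40, 3))
        o_lag = rng.standard_normal((40, 3))
        p = pooled_from(f, o_t, o_lag)
        c_fo, c_oo = loop_covariances(f, o_t, o_lag)
        expect = c_fo @ np.linalg.inv(c_oo)
        assert np.allclose(estimate_response(p), expect, atol=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(60)
        o_t = rng.standard_normal((60, 2))
        o_lag = rng.standard_normal((60, 2))
        r = estimate_response(pooled_from(f, o_t, o_lag))
        r_scaled = estimate_response(pooled_from(3.0 * f, o_t, o_lag))
        assert np.allclose(r_scaled, 3.0 * r, atol=1e-10)
        # scaling a forcing column divides its response
        r_col = estimate_response(pooled_from(f, o_t * [2.0, 1.0], o_lag * [2.0, 1.0]))
        assert r_col[0] == pytest.approx(r[0] / 2.0, abs=1e-10)

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(5)
        p = pooled_from(rng.standard_normal(5), rng.standard_normal((5, 4)),
                        rng.standard_normal((5, 4)))
        with pytest.raises(ValueError, match="insufficient"):
            estimate_response(p)


class TestAic:
    def _pooled(self, seed=6, n=100, k=3):
        rng = np.random.default_rng(seed)
        o = rng.standard_normal((n + 1, k))
        f = o[1:, 0] * 1.0 + 0.5 * rng.standard_normal(n)
        return pooled_from(f, o[1:], o[:-1])

    def test_null_model_formula(self):
        p = self._pooled()
        f = p.f - p.f.mean()
        p2 = pooled_from(f, p.o_t, p.o_lag)
        n = len(f)
        expect = n * np.log(np.var(f, ddof=1) * (n - 1) / n) + 2
        assert aic_score(p2, None) == pytest.approx(expect, abs=1e-10)

    def test_duplicate_forcing_pays_penalty_of_two(self):
        # identical RSS, one extra parameter -> AIC greater by exactly 2
        p = self._pooled(k=1)
        dup = pooled_from(p.f, np.hstack([p.o_t, p.o_t]), np.hstack([p.o_lag, p.o_lag]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1 = aic_score(dup, [0])
            a2 = aic_score(dup, [0, 1])
        assert a2 - a1 == pytest.approx(2.0, abs=1e-6)

    def test_noise_forcing_raises_aic_in_expectation(self):
        diffs = []
        for seed in range(30):
            p = self._pooled(seed=seed)
            diffs.append(aic_score(p, [0, 1]) - aic_score(p, [0]))
        assert np.mean(diffs) > 0  # adding a pure-noise forcing hurts on average

    def test_zero_rss_guard(self):
        o = np.random.default_rng(8).standard_normal((50, 1))
        p = pooled_from(2 * o[:, 0], o, o)
        with pytest.warns(RuntimeWarning, match="zero residual"):
            assert aic_score(p, [0]) == -np.inf


class TestBackwardStepwise:
    def test_single_exact_candidate_retained(self):
        o = np.random.default_rng(9).standard_normal((60, 1))
        p = pooled_from(o[:, 0], o, np.roll(o, 1, axis=0))
        idx, r = backward_stepwise(p)
        assert list(idx) == [0]

    def test_support_recovery_two_strong_of_four(self):
        # two true effects |R| >= 0.5 among four candidates, n = 240
        hits = 0
        for rep in range(100):
            cfg = SynthConfig(
                n_forcings=4, n_years=20, ar1_coeffs=[0.7] * 4,
                forcing_corr=np.eye(4), true_response=[1.0, -0.6, 0.0, 0.0],
                fire_noise_sd=1.0, seed=1000 + rep,
                seasonal_cycle={"fire": np.zeros(12)}, trend_slope={"fire": 0.0},
            )
            o = gen_forcings(cfg).to_numpy()
            fire, _ = gen_fire_series(gen_forcings(cfg), cfg)
            p = pooled_from(fire.values[1:], o[1:], o[:-1])
            idx, _ = backward_stepwise(p)
            if {0, 1} <= set(idx):
                hits += 1
        assert hits >= 90

    def test_all_noise_retains_little(self):
        retained = []
        rng = np.random.default_rng(10)
        for _ in range(100):
            f = rng.standard_normal(240)
            o = np.zeros((241, 4))
            for t in range(1, 241):
                o[t] = 0.7 * o[t - 1] + rng.standard_normal(4) * np.sqrt(1 - 0.49)
            p = pooled_from(f, o[1:], o[:-1])
            idx, _ = backward_stepwise(p)
            retained.append(len(idx))
        assert np.median(retained) <= 1

    def test_aic_nonincreasing_along_path(self):
        rng = np.random.default_rng(11)
        o = rng.standard_normal((121, 6))
        f = o[1:, 0] + rng.standard_normal(120)
        p = pooled_from(f, o[1:], o[:-1])
        idx, _ = backward_stepwise(p)
        assert aic_score(p, idx) <= aic_score(p, np.arange(6)) + 1e-10


class TestBootstrap:
    def _signal_pooled(self, seed=12):
        rng = np.random.default_rng(seed)
        n = 120
        o = np.zeros(n + 1)
        for t in range(1, n + 1):
            o[t] = 0.8 * o[t - 1] + rng.standard_normal() * 0.6
        f = 2.0 * o[1:] + 0.2 * rng.standard_normal(n)
        return pooled_from(f, o[1:, None], o[:-1, None])

    def test_strong_signal_is_significant(self):
        p = self._signal_pooled()
        r = estimate_response(p)
        pv = bootstrap_significance(p, np.array([0]), r, n_iter=500,
                                    rng=np.random.default_rng(0))
        assert pv[0] < 0.1

    def test_identical_seed_identical_pvalues(self):
        p = self._signal_pooled()
        r = estimate_response(p)
        pv1 = bootstrap_significance(p, np.array([0]), r, n_iter=300,
                                     rng=np.random.default_rng(5))
        pv2 = bootstrap_significance(p, np.array([0]), r, n_iter=300,
                                     rng=np.random.default_rng(5))
        assert (pv1 == pv2).all()

    def test_pvalues_have_continuity_floor(self):
        p = self._signal_pooled()
        r = estimate_response(p)
        pv = bootstrap_significance(p, np.array([0]), r, n_iter=200,
                                    rng=np.random.default_rng(1))
        assert pv[0] >= 1.0 / 201.0

    def test_small_iteration_count_warns(self):
        p = self._signal_pooled()
        r = estimate_response(p)
        with pytest.warns(RuntimeWarning, match="n_iter"):
            bootstrap_significance(p, np.array([0]), r, n_iter=50,
                                   rng=np.random.default_rng(2))


class TestIdentificationAssumption:
    def test_noise_uncorrelated_with_lagged_forcings(self):
        # C_NO(tau) ~ 0: the generator satisfies the estimator's key assumption
        cfg = SynthConfig(seed=33, n_years=200)
        o = gen_forcings(cfg)
        _, noise = gen_fire_series(o, cfg)
        ov = o.to_numpy()
        n = len(noise) - 1
        c_no = (noise.values[1:] - noise.values[1:].mean()) @ (
            ov[:-1] - ov[:-1].mean(0)
        ) / (n - 1)
        assert np.abs(c_no).max() < 3 / np.sqrt(n)


class TestSeasonalCycleAndSummaries:
    def _make_estimate(self, season, labels, resp, pvals):
        from sgefa import season_window

        return FeedbackEstimate(
            labels=labels,
            retained=pd.Series([l in resp for l in labels], index=labels),
            response=pd.Series(resp),
            p_value=pd.Series(pvals),
            tau=1, season=season_window(season), n_samples=60,
        )

    def test_max_response_season_rules(self):
        labels = ["A", "B"]
        cyc = {
            1: self._make_estimate(1, labels, {"A": 0.3}, {"A": 0.05}),
            2: self._make_estimate(2, labels, {"A": -0.5}, {"A": 0.02}),
            3: self._make_estimate(3, labels, {"A": 0.9}, {"A": 0.5}),  # insignificant
        }
        season, value = max_response_season(cyc, "A")
        assert season == 2 and value == -0.5  # sign preserved, p<0.1 only
        assert max_response_season(cyc, "B") is None

    def test_robustness_count_matrix(self):
        labels = ["A", "B"]
        sig = self._make_estimate(1, labels, {"A": 0.4}, {"A": 0.01})
        insig = self._make_estimate(1, labels, {"A": 0.4}, {"A": 0.6})
        counts = robustness_count([{1: sig}, {1: sig}, {1: insig}])
        assert counts.loc[1, "A"] == 2
        assert counts.loc[1, "B"] == 0

    def test_seasonally_modulated_truth_localizes_significance(self):
        # forcing drives fire only in months 6-8: seasons overlapping those
        # months carry the significant responses
        rng = np.random.default_rng(14)
        n = 12 * 40
        idx = pd.period_range("1980-01", periods=n, freq="M")
        o = np.zeros(n)
        for t in range(1, n):
            o[t] = 0.8 * o[t - 1] + rng.standard_normal() * 0.6
        active = np.isin(idx.month, [6, 7, 8])
        fire = pd.Series(np.where(active, 1.5 * o, 0.0) + 0.5 * rng.standard_normal(n),
                         index=idx)
        odf = pd.DataFrame({"X": o}, index=idx)
        cyc = seasonal_feedback_cycle(fire, odf, tau=1, n_iter=300,
                                      rng=np.random.default_rng(0), min_samples=10)
        sig_seasons = {
            s for s, est in cyc.items()
            if est.retained["X"] and est.p_value["X"] < 0.1
        }
        overlapping = {4, 5, 6, 7, 8}  # 3-month windows touching Jun-Aug
        assert sig_seasons
        assert sig_seasons <= overlapping

    def test_each_season_uses_at_most_three_pairs_per_year(self, default_bundle):
        b = default_bundle
        from sgefa import anomalize, pool_season, season_window

        fire = anomalize(b.fire)
        for s in (1, 6, 12):
            pooled = pool_season(fire, b.forcings, season_window(s), tau=1)
            assert len(pooled.f) <= 3 * b.truth.n_years


class TestSpatialResponseMap:
    def test_opposite_sign_regions_recovered(self):
        rng = np.random.default_rng(15)
        n = 240
        idx = pd.period_range("1997-01", periods=n, freq="M")
        o = np.zeros(n)
        for t in range(1, n):
            o[t] = 0.8 * o[t - 1] + rng.standard_normal() * 0.6
        odf = pd.DataFrame({"X": o}, index=idx)
        vals = np.empty((n, 2, 2))
        for i in range(2):
            sign = 1.0 if i == 0 else -1.0
            for j in range(2):
                vals[:, i, j] = sign * 1.5 * o + 0.3 * rng.standard_normal(n)
        field = make_field(vals, [0, 10], [0, 10], start="1997-01")
        ds = spatial_response_map(field, odf, tau=1, n_iter=300,
                                  rng=np.random.default_rng(0))
        resp = ds["response"].values[0]
        assert (resp[0] > 0).all() and (resp[1] < 0).all()

    def test_uniform_truth_gives_near_constant_map(self):
        rng = np.random.default_rng(16)
        n = 240
        idx = pd.period_range("1997-01", periods=n, freq="M")
        o = np.zeros(n)
        for t in range(1, n):
            o[t] = 0.8 * o[t - 1] + rng.standard_normal() * 0.6
        odf = pd.DataFrame({"X": o}, index=idx)
        vals = (2.0 * o[:, None, None] + 0.2 * rng.standard_normal((n, 2, 2)))
        field = make_field(vals, [0, 10], [0, 10], start="1997-01")
        ds = spatial_response_map(field, odf, tau=1, n_iter=300,
                                  rng=np.random.default_rng(0))
        resp = ds["response"].values[0]
        assert np.isfinite(resp).all()
        assert resp.max() - resp.min() < 0.5


def test_assess_feedback_reports_absent_not_zero():
    rng = np.random.default_rng(17)
    o = rng.standard_normal((121, 3))
    f = o[1:, 0] * 2 + 0.5 * rng.standard_normal(120)
    p = pooled_from(f, o[1:], o[:-1])
    est = assess_feedback(p, ["A", "B", "C"], n_iter=300,
                          rng=np.random.default_rng(3))
    dropped = [l for l in est.labels if not est.retained[l]]
    for l in dropped:
        assert l not in est.response.index  # absent, not zero
    assert ((est.p_value >= 0) & (est.p_value <= 1)).all()


class TestBlockPermutation:
    def test_block_option_preserves_marginal_and_detects_signal(self):
        rng = np.random.default_rng(21)
        n = 120
        o = np.zeros(n + 1)
        for t in range(1, n + 1):
            o[t] = 0.8 * o[t - 1] + rng.standard_normal() * 0.6
        f = 2.0 * o[1:] + 0.3 * rng.standard_normal(n)
        p = pooled_from(f, o[1:, None], o[:-1, None])
        r = estimate_response(p)
        pv = bootstrap_significance(p, np.array([0]), r, n_iter=300,
                                    rng=np.random.default_rng(0), block=12)
        assert pv[0] < 0.1

    def test_block_permutation_is_multiset_preserving(self):
        from sgefa.feedback import _block_permutation

        perm = _block_permutation(50, 12, np.random.default_rng(1))
        assert sorted(perm) == list(range(50))
        # within-block order preserved for a full block
        start = list(perm).index(12)
        assert list(perm[start:start + 12]) == list(range(12, 24))
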