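"""Behavioral statistics: outcome classification, binning, false-alarm
hazard, time-resolved d', Erlang dynamics fits and reaction-time ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.stats import mannwhitneyu, norm

from tonecloud import behavior as bh


class TestClassification:
    @pytest.mark.parametrize("ct, rt, outcome, reaction", [
        (3.0, 2.1, "false_alarm", None),
        (3.0, 4.2, "hit", 1.2),
        (3.0, 5.6, "miss", None),      # 0.6 s beyond the 2 s window
        (3.0, 5.0, "hit", 2.0),        # window edge is inclusive
        (3.0, 3.0, "false_alarm", None),
        (3.0, None, "miss", None),
    ])
    def test_examples(self, ct, rt, outcome, reaction):
        out, r = bh.classify_trial(ct, rt)
        assert out == outcome
        if reaction is None:
            assert r is None
        else:
            assert r == pytest.approx(reaction)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            bh.classify_trial(3.0, -0.5)
        with pytest.raises(ValueError):
            bh.classify_trial(-1.0, 0.5)

    @settings(max_examples=200, deadline=None)
    @given(ct=hst.floats(0, 8), rt=hst.one_of(hst.none(), hst.floats(0, 12)))
    def test_outcomes_partition(self, ct, rt):
        out, reaction = bh.classify_trial(ct, rt)
        assert out in ("hit", "miss", "false_alarm")
        if out == "hit":
            assert ct < rt <= ct + 2 and reaction == rt - ct
        elif out == "false_alarm":
            assert rt is not None and rt <= ct
        else:
            assert rt is None or rt > ct + 2 or np.isnan(rt)


class TestChangeTimeBinning:
    def test_exponential_edges_equalize_counts(self, rng):
        draws = rng.exponential(3.2, 40_000)
        draws = draws[draws <= 8][:10_000]
        edges, assign = bh.bin_change_times(draws, 6)
        counts = np.bincount(assign, minlength=6)
        assert counts.max() / counts.min() < 1.3
        assert np.all(np.diff(np.diff(edges)) > 0)     # widths increase

    def test_single_bin_contains_everything(self, rng):
        times = rng.uniform(0, 8, 50)
        edges, assign = bh.bin_change_times(times, 1)
        assert np.all(assign == 0)

    def test_quantile_bins_match_quartiles(self, rng):
        times = rng.exponential(3.2, 4000) % 8
        edges, assign = bh.bin_change_times(times, 4, method="quantile")
        counts = np.bincount(assign, minlength=4)
        assert counts.max() - counts.min() <= 2

    def test_fewer_trials_than_bins_rejected(self):
        with pytest.raises(ValueError):
            bh.bin_change_times(np.array([1.0, 2.0]), 4)


class TestFalseAlarmRate:
    def test_no_false_alarms_gives_zero_curve(self):
        df = pd.DataFrame({"change_time": np.full(100, 6.0),
                           "response_time": np.full(100, np.nan)})
        out = bh.instantaneous_fa_rate(df, dt=0.5)
        assert np.nansum(out.fa_rate) == 0

    def test_constant_hazard_responder_is_flat_at_p_over_dt(self, rng):
        # geometric pressing with probability p per dt bin -> rate = p/dt
        p, dt, n = 0.05, 0.25, 40_000
        ct = np.full(n, 8.0)
        k = rng.geometric(p, n)
        rt = np.where(k * dt <= 8.0, k * dt - dt / 2, np.nan)
        out = bh.instantaneous_fa_rate(pd.DataFrame({"change_time": ct, "response_time": rt}), dt=dt)
        rates = out.fa_rate.to_numpy()[:24]
        assert np.nanmax(np.abs(rates - p / dt)) < 0.2 * p / dt

    def test_empty_risk_set_is_missing(self):
        df = pd.DataFrame({"change_time": [1.0], "response_time": [np.nan]})
        out = bh.instantaneous_fa_rate(df, dt=0.5)
        assert np.isnan(out.fa_rate.to_numpy()[-1])


class TestTimeDependentDPrime:
    def test_equal_rates_cancel(self):
        # engineered HR(2.0) = FAR(2.0) -> d' = 0 at that grid point
        df = _engineered_records(hr=0.5, far=0.5)
        curve = bh.time_dependent_dprime(df)
        k = np.where(np.isclose(curve.t, 2.0))[0][0]
        assert curve.dprime[k] == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_arithmetic(self):
        # HR = 0.84, FAR = 0.16 -> d' = Z(0.84) - Z(0.16) = 1.9889
        df = _engineered_records(hr=0.84, far=0.16)
        curve = bh.time_dependent_dprime(df)
        k = np.where(np.isclose(curve.t, 2.0))[0][0]
        assert curve.hr[k] == pytest.approx(0.84)
        assert curve.far[k] == pytest.approx(0.16)
        assert curve.dprime[k] == pytest.approx(1.9889, abs=1e-3)

    def test_antisymmetry_under_rate_swap(self):
        a = bh.time_dependent_dprime(_engineered_records(hr=0.8, far=0.3))
        b = bh.time_dependent_dprime(_engineered_records(hr=0.3, far=0.8))
        k = np.where(np.isclose(a.t, 2.0))[0][0]
        assert a.dprime[k] == pytest.approx(-b.dprime[k])

    def test_bootstrap_bounds_bracket_the_point_estimate(self, rng):
        df = _engineered_records(hr=0.7, far=0.2)
        curve = bh.time_dependent_dprime(df, n_boot=200, rng=rng)
        k = np.where(np.isclose(curve.t, 2.0))[0][0]
        assert curve.ci_lo[k] < curve.dprime[k] < curve.ci_hi[k]


def _engineered_records(hr: float, far: float) -> pd.DataFrame:
    """Trials pinning HR and FAR at the t = 2.0 s grid point: 100 trials
    changing at 2.1 s with the given hit fraction, 400 long trials of which
    a fraction presses inside the (2, 4] s no-change window."""
    n_h, n_f = 100, 400
    rows = []
    for i in range(n_h):
        rows.append({"change_time": 2.1,
                     "response_time": 2.6 if i < round(hr * n_h) else np.nan})
    for i in range(n_f):
        rows.append({"change_time": 7.9,
                     "response_time": 3.0 if i < round(far * n_f) else np.nan})
    return pd.DataFrame(rows)


class TestErlangFit:
    def test_curve_starts_at_p0(self):
        assert bh.erlang_cdf(0.0, 0.07, 0.8, 1.0, 3) == pytest.approx(0.07)
        assert bh.erlang_cdf(1e9, 0.07, 0.8, 1.0, 3) == pytest.approx(0.87)

    def test_large_n_recovery_is_unbiased(self):
        # noise -> 0: shape and rate recovered essentially exactly
        t = np.array([0.4, 1.0, 1.8, 2.8, 4.2, 6.4])
        rows = [{"size": s, "t": tt, "performance": bh.erlang_cdf(tt, 0.05, 0.85, tau, 2),
                 "n_trials": 10_000}
                for s, tau in [(50, 1.2), (140, 0.5)] for tt in t]
        fit = bh.fit_erlang_cdf(pd.DataFrame(rows))
        assert fit.k == 2
        assert fit.tau(50) == pytest.approx(1.2, rel=0.02)
        assert fit.tau(140) == pytest.approx(0.5, rel=0.02)

    def test_binomial_noise_recovery_within_bootstrap_ci(self, rng):
        # 30 trials per bin across four change sizes sharing the shape k; the
        # true curves must fall inside the parametric bootstrap band of the
        # fitted curves (k is searched globally, so the comparison is done in
        # curve space where k and tau trade off)
        t = np.array([0.4, 1.0, 1.8, 2.8, 4.2, 6.4])
        taus = {50: 1.2, 80: 0.9, 110: 0.7, 140: 0.5}

        def gen(curves):
            rows = [{"size": s, "t": tt, "performance": rng.binomial(30, c) / 30,
                     "n_trials": 30}
                    for s, cv in curves.items() for tt, c in zip(t, cv)]
            return pd.DataFrame(rows)

        true_curves = {s: bh.erlang_cdf(t, 0.05, 0.85, tau, 2) for s, tau in taus.items()}
        fit = bh.fit_erlang_cdf(gen(true_curves))
        fitted_curves = {s: fit.predict(s, t) for s in taus}
        boots = np.array([
            np.concatenate([bh.fit_erlang_cdf(gen(fitted_curves)).predict(s, t)
                            for s in taus])
            for _ in range(100)])
        lo, hi = np.percentile(boots, [0.5, 99.5], axis=0)
        truth = np.concatenate([true_curves[s] for s in taus])
        covered = (truth >= lo - 1e-9) & (truth <= hi + 1e-9)
        assert covered.mean() >= 23 / 24

    def test_tau_ordering_preserved(self, rng):
        t = np.array([0.4, 1.0, 1.8, 2.8, 4.2, 6.4])
        taus = {50: 1.2, 80: 0.9, 110: 0.7, 140: 0.5}
        rows = [{"size": s, "t": tt,
                 "performance": np.clip(bh.erlang_cdf(tt, 0.05, 0.85, tau, 2)
                                        + rng.normal(0, 0.02), 0, 1),
                 "n_trials": 30}
                for s, tau in taus.items() for tt in t]
        fit = bh.fit_erlang_cdf(pd.DataFrame(rows))
        fitted = [fit.tau(s) for s in (50, 80, 110, 140)]
        assert np.all(np.diff(fitted) < 0)

    def test_too_few_bins_rejected(self):
        df = pd.DataFrame({"size": [50] * 3, "t": [1, 2, 3], "performance": [0.2, 0.5, 0.7],
                           "n_trials": 30})
        with pytest.raises(ValueError):
            bh.fit_erlang_cdf(df)


class TestAuroc:
    def test_identical_distributions_are_chance(self, rng):
        x = rng.uniform(0.3, 1.8, 200)
        area, _, _ = bh.auroc(x, x.copy())
        assert area == pytest.approx(0.5, abs=0.02)

    def test_perfect_separation(self):
        hits = np.array([0.3, 0.4, 0.5])
        fas = np.array([1.5, 1.7, 1.9])
        area, _, _ = bh.auroc(hits, fas)
        assert area == pytest.approx(1.0)

    def test_matches_pairwise_mann_whitney_oracle(self, rng):
        # on small samples with a fine grid the trapezoid area equals the
        # exhaustive pairwise comparison P(hit RT < FA RT)
        hits = rng.uniform(0.2, 1.9, 8)
        fas = rng.uniform(0.2, 1.9, 7)
        fine = np.unique(np.concatenate([hits, fas]))
        area, _, _ = bh.auroc(hits, fas, t_grid=fine)
        u = mannwhitneyu(fas, hits).statistic / (hits.size * fas.size)
        assert area == pytest.approx(u, abs=1e-12)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            bh.auroc(np.array([]), np.array([1.0]))

    def test_by_change_size_on_model_records(self, dual_records):
        out = bh.auroc_by_change_size(dual_records)
        assert set(out["size"]) == {50, 80, 110, 140}
        assert out["auroc"].between(0, 1).all()


def test_fa_pseudo_reaction_times_live_in_the_window(dual_records):
    rts = bh.fa_pseudo_reaction_times(dual_records)
    assert rts.size > 0
    assert np.all((rts > 0) & (rts <= 2.0))


def test_performance_table_counts_are_consistent(dual_records):
    table = bh.performance_table(dual_records, n_time_bins=4)
    assert (table["hits"] + table["misses"] + table["false_alarms"]
            == table["n_trials"]).all()
    ok = table["performance"].dropna()
    assert ok.between(0, 1).all()
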