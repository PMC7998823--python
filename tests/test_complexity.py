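"""Fractal dimensions, scaling exponents, chaos diagnostics, LZ76, RQA
and Poincaré geometry, cross-checked against brute-force oracles and
known asymptotics."""

import math

import numpy as np
import pytest

from ceps.complexity import (
    allan_factor,
    correlation_dimension,
    dfa,
    higuchi_fd,
    hurst_rs,
    katz_fd,
    largest_lyapunov,
    lempel_ziv,
    lz76_count,
    multiscale_lz,
    poincare_lagged,
    rqa_metrics,
    symbolize,
)
from ceps.complexity import _pairwise_cheb_counts
from ceps.embedding import delay_embed
from ceps.synthetic import gen_fgn, gen_logistic, gen_noise

from oracles import d2_pair_counts_oracle, lz76_oracle, rqa_oracle


class TestHiguchiFD:
    def test_line_has_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0), k_max=8) == pytest.approx(1.0, abs=0.01)

    def test_white_noise_approaches_two(self):
        vals = [higuchi_fd(gen_noise("white", 5000, s), k_max=10) for s in range(20)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_fbm_matches_two_minus_hurst(self):
        for H in (0.3, 0.5, 0.7):
            vals = [
                higuchi_fd(np.cumsum(gen_fgn(H, 2**13, s)), k_max=10) for s in range(5)
            ]
            assert np.mean(vals) == pytest.approx(2 - H, abs=0.1)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.ones(1000), k_max=8)


class TestKatzFD:
    def test_monotone_ramp_is_one(self):
        assert katz_fd(np.linspace(0, 5, 200)) == pytest.approx(1.0, abs=1e-9)

    def test_alternating_series_direct_formula(self):
        x = np.tile([0.0, 1.0], 51)[:101]
        L = np.abs(np.diff(x)).sum()
        d = np.abs(x[1:] - x[0]).max()
        expected = math.log(100) / (math.log(100) + math.log(d / L))
        assert katz_fd(x) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=300)
        assert katz_fd(17.3 * x) == pytest.approx(katz_fd(x), rel=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            katz_fd(np.ones(10))


class TestHurstRS:
    def test_white_noise_near_half(self):
        vals = [hurst_rs(gen_noise("white", 10_000, s)) for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_fgn_parameter_recovery(self):
        vals = [hurst_rs(gen_fgn(0.8, 2**13, s)) for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.1)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            hurst_rs(np.ones(1000))


class TestDFA:
    def test_white_noise_alpha_half(self):
        vals = [dfa(gen_noise("white", 10_000, s)).alpha for s in range(20)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_brownian_alpha_three_halves(self):
        vals = [dfa(np.cumsum(gen_noise("white", 10_000, s))).alpha for s in range(20)]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_brute_force_window_fit_agreement(self, rng):
        # independent re-computation of F(s) with explicit per-window polyfits
        x = rng.standard_normal(600)
        res = dfa(x, scales=[8, 16, 32], order=1)
        y = np.cumsum(x - x.mean())
        for s_idx, s in enumerate([8, 16, 32]):
            resids = []
            for w in range(len(y) // s):
                seg = y[w * s : (w + 1) * s]
                t = np.arange(s)
                coef = np.polyfit(t, seg, 1)
                resids.extend(seg - np.polyval(coef, t))
            f = np.sqrt(np.mean(np.square(resids)))
            assert res.fluctuation[s_idx] == pytest.approx(f, rel=1e-9)

    def test_pure_trend_degenerate(self):
        # the profile of a linear ramp is quadratic, so order-2 window
        # fits remove it exactly and the log-fluctuation degenerates
        with pytest.raises(ValueError):
            dfa(np.arange(1000.0), scales=[8, 16, 32], order=2)

    def test_hurst_alpha_consistency_on_fgn(self):
        for H in (0.3, 0.7):
            hs = [hurst_rs(gen_fgn(H, 2**13, s)) for s in range(10)]
            als = [dfa(gen_fgn(H, 2**13, s)).alpha for s in range(10)]
            assert abs(np.mean(hs) - np.mean(als)) < 0.1


class TestAllanFactor:
    def test_poisson_process_unity(self):
        vals = []
        for s in range(10):
            rng = np.random.default_rng(s)
            iv = rng.exponential(1.0, 10_000)
            vals.append(allan_factor(iv, [1.0, 10.0, 100.0]))
        mean = np.mean(vals, axis=0)
        np.testing.assert_allclose(mean, 1.0, atol=0.15)

    def test_periodic_events_vanish(self):
        af = allan_factor(np.full(1000, 1.0), [50.0, 100.0])
        assert np.all(af < 0.05)

    def test_single_window_errors(self):
        with pytest.raises(ValueError):
            allan_factor(np.full(100, 1.0), [100.0])


class TestCorrelationDimension:
    def test_uniform_1d_space_filling(self, rng):
        x = rng.uniform(size=5000)
        res = correlation_dimension(x, m=1, tau=1)
        assert res.d2 == pytest.approx(1.0, abs=0.1)

    def test_pair_counts_match_double_loop(self, rng):
        x = rng.normal(size=200)
        radii = x.std() * np.array([0.2, 0.5, 1.0])
        emb = delay_embed(x, 2, 1)
        counts, total = _pairwise_cheb_counts(emb, radii, theiler_w=3)
        o_counts, o_total = d2_pair_counts_oracle(x, 2, 1, radii, theiler_w=3)
        assert total == o_total
        np.testing.assert_array_equal(counts, o_counts)

    def test_correlation_sum_monotone_bounded(self, rng):
        res = correlation_dimension(rng.normal(size=800), m=2, tau=1)
        assert np.all(np.diff(res.corr_sum) >= 0)
        assert res.corr_sum[-1] <= 1.0


class TestLyapunov:
    def test_logistic_map_ln2(self):
        vals = [
            largest_lyapunov(gen_logistic(3000, s), m=2, tau=1, mean_period=10,
                             fit_range=(0, 5)).lle
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(math.log(2), abs=0.1)

    def test_periodic_signal_near_zero(self):
        # tiny observational noise keeps neighbour distances above float
        # noise; the fit starts after the first decorrelation step
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * np.arange(1500) / 26.7) + rng.normal(0, 1e-3, 1500)
        res = largest_lyapunov(x, m=2, tau=7, mean_period=27, fit_range=(1, 10))
        assert abs(res.lle) < 0.02

    def test_fit_range_outside_curve_errors(self, rng):
        with pytest.raises(ValueError):
            largest_lyapunov(rng.normal(size=300), m=2, tau=1, mean_period=5,
                             max_iter=10, fit_range=(200, 210))


class TestLempelZiv:
    def test_alternating_sequence_low_complexity(self):
        x = np.tile([0.0, 1.0], 500)
        assert lempel_ziv(x) < 0.1

    def test_random_binary_normalizes_to_one(self):
        x = gen_noise("white", 100_000, seed=5)
        assert lempel_ziv(x) == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(8))
    def test_phrase_count_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sym = rng.integers(0, 2, size=int(rng.integers(10, 400)))
        assert lz76_count(sym.tolist()) == lz76_oracle(sym)

    def test_multiscale_scale1_equals_plain(self, rng):
        x = rng.normal(size=400)
        assert multiscale_lz(x, [1])[0] == lempel_ziv(x)

    def test_tertile_symbolizer(self, rng):
        x = rng.normal(size=300)
        sym = symbolize(x, "tertile")
        assert set(np.unique(sym)) == {0, 1, 2}
        counts = np.bincount(sym)
        assert np.all(np.abs(counts - 100) <= 2)


class TestRQA:
    def test_pure_sine_highly_deterministic(self):
        x = np.sin(2 * np.pi * np.arange(1000) / 40)
        res = rqa_metrics(x, m=2, tau=10, radius_frac=0.3)
        assert res.det > 0.95

    def test_iid_noise_low_determinism(self, rng):
        x = rng.standard_normal(200)
        res = rqa_metrics(x, m=2, tau=1, radius_frac=0.35, min_line=2)
        assert res.det < 0.3

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        res = rqa_metrics(x, m=2, tau=2, radius_frac=0.4, min_line=2)
        o = rqa_oracle(x, m=2, tau=2, radius_frac=0.4, min_line=2)
        assert res.rr == pytest.approx(o["rr"], abs=1e-12)
        assert res.det == pytest.approx(o["det"], abs=1e-12)
        assert res.ent == pytest.approx(o["ent"], abs=1e-12)
        assert res.lmax == o["lmax"]
        assert res.lam == pytest.approx(o["lam"], abs=1e-12)
        assert res.tt == pytest.approx(o["tt"], abs=1e-12)

    def test_equal_line_lengths_zero_entropy(self):
        # one repeated motif in distinct surroundings: every diagonal line
        # has the same length, so the line-length distribution is a
        # single category
        x = np.array([0.0, 1.0, 2.0, 50.0, 0.0, 1.0, 2.0, 90.0])
        res = rqa_metrics(x, m=1, tau=1, radius_frac=0.01, min_line=2)
        assert res.det == 1.0
        assert res.ent == 0.0

    def test_empty_matrix_warns_zero(self, rng):
        x = rng.normal(size=60)
        with pytest.warns(UserWarning):
            res = rqa_metrics(x, m=2, tau=1, radius_frac=1e-9)
        assert res.rr == 0.0 and res.det == 0.0


class TestPoincare:
    def test_sd1_closed_form_lag1(self, rng):
        x = rng.normal(800, 50, 500)
        res = poincare_lagged(x, lags=[1])[0]
        assert res.sd1 == pytest.approx(np.sqrt(np.var(np.diff(x)) / 2), rel=1e-12)

    def test_alternating_hand_value(self):
        x = np.tile([800.0, 810.0], 101)[:201]  # balanced up/down diffs
        res = poincare_lagged(x, lags=[1])[0]
        assert res.sd1 == pytest.approx(np.sqrt(100 / 2), rel=1e-9)

    def test_periodic_series_zero_sd1_at_period(self):
        x = np.tile([800.0, 900.0, 850.0], 50)
        res = poincare_lagged(x, lags=[3])[0]
        assert res.sd1 == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_flagged(self):
        res = poincare_lagged(np.full(50, 800.0), lags=[1])[0]
        assert res.sd1 == 0.0 and np.isnan(res.ccm)

    def test_lag_range_returns_all(self, rri_like):
        out = poincare_lagged(rri_like, lags=range(1, 11))
        assert [r.lag for r in out] == list(range(1, 11))
        assert all(np.isfinite(r.ccm) for r in out)
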