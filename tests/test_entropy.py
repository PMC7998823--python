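"""Entropy battery: oracle equivalence, hand-worked values and
analytic invariants."""

import math

import numpy as np
import pytest

from ceps.entropy import (
    bubble_entropy,
    conditional_entropy,
    dispersion_entropy,
    dispersion_pattern_probs,
    distribution_entropy,
    entropy_of_entropy,
    ordinal_family,
    phase_entropy,
    regularity_family,
    sample_entropy_counts,
    shannon_like,
    slope_entropy,
    swap_count,
    tone_entropy,
    _slope_symbols,
)

from oracles import (
    apen_oracle,
    dispersion_census_oracle,
    disten_oracle,
    eoe_oracle,
    sampen_counts_oracle,
    swap_count_oracle,
)


class TestShannonLike:
    def test_uniform_bins_give_ln_k(self):
        # 4 equal-mass bins over [0, 4)
        x = np.repeat([0.5, 1.5, 2.5, 3.5], 25)
        assert shannon_like(x, "shannon", bins=4) == pytest.approx(math.log(4))

    def test_renyi_q_to_one_limit(self):
        x = np.repeat([0.0, 1.0, 1.0, 2.0], 10)
        se = shannon_like(x, "shannon", bins=3)
        re = shannon_like(x, "renyi", bins=3, q=1.001)
        assert abs(re - se) < 1e-3

    def test_hand_values_q2(self):
        # p = (0.25, 0.75): Renyi2 = ln(1/0.625), Tsallis2 = 0.375
        x = np.array([0.0] * 10 + [1.0] * 30)
        assert shannon_like(x, "renyi", bins=2, q=2) == pytest.approx(
            math.log(1 / 0.625), rel=1e-12
        )
        assert shannon_like(x, "tsallis", bins=2, q=2) == pytest.approx(0.375)

    def test_constant_series_zero(self):
        assert shannon_like(np.full(100, 2.0), "shannon", bins=8) == 0.0


class TestConditionalEntropy:
    def test_iid_symbols_match_marginal(self, rng):
        x = rng.uniform(size=30_000)
        ce = conditional_entropy(x, m=2, bins=4)
        assert ce == pytest.approx(math.log(4), rel=0.05)

    def test_period2_deterministic_zero(self):
        x = np.tile([1.0, 5.0], 200)
        # word counts differ by one between the two alternating patterns,
        # so CE vanishes only to the resolution of that imbalance
        assert conditional_entropy(x, m=2, bins=2) == pytest.approx(0.0, abs=1e-3)

    def test_all_unique_words_saturate_correction(self, rng):
        # long words on a short i.i.d. series: every word unique
        x = rng.normal(size=80)
        cce = conditional_entropy(x, m=7, bins=8, corrected=True)
        ce = conditional_entropy(x, m=7, bins=8, corrected=False)
        from ceps.entropy import _quantile_symbols, _word_probs, _shannon

        sym = _quantile_symbols(x, 8)
        h1 = _shannon(_word_probs(sym, 1)[0])
        assert cce == pytest.approx(ce + h1, rel=1e-12)


class TestRegularityFamily:
    def test_periodic_sampen_exactly_zero(self):
        x = np.tile([1.0, 2.0, 3.0], 100)
        assert regularity_family(x, "sampen", m=2, r=0.2) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_sampen_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=200)
        r_abs = 0.2 * x.std()
        a, b = sample_entropy_counts(x, 2, r_abs)
        oa, ob = sampen_counts_oracle(x, 2, r_abs)
        assert (a, b) == (oa, ob)

    def test_tree_and_brute_pair_counts_agree(self, rng):
        # the KD-tree path used for long series must equal the broadcast path
        x = rng.normal(size=1800)
        r_abs = 0.2 * x.std()
        from ceps.entropy import _pair_count_brute, _pair_count_tree
        from ceps.embedding import delay_embed

        t = delay_embed(x, 2, 1)[:-1]
        assert _pair_count_brute(t, r_abs) == _pair_count_tree(t, r_abs)

    @pytest.mark.parametrize("seed", range(3))
    def test_apen_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=120)
        r_abs = 0.2 * x.std()
        got = regularity_family(x, "apen", m=2, r_abs=r_abs)
        assert got == pytest.approx(apen_oracle(x, 2, r_abs), abs=1e-12)

    def test_apen_nonnegative_near_sampen(self, rng):
        x = rng.uniform(size=1000)
        ap = regularity_family(x, "apen", m=2, r=0.2)
        sa = regularity_family(x, "sampen", m=2, r=0.2)
        assert ap >= 0
        assert ap < sa  # self-match bias lowers ApEn
        assert abs(ap - sa) < 0.5

    def test_qse_cosen_offsets(self, rng):
        x = rng.normal(900, 40, 400)
        r_abs = 0.2 * x.std()
        sa = regularity_family(x, "sampen", m=2, r=0.2)
        qse = regularity_family(x, "qse", m=2, r=0.2)
        cos = regularity_family(x, "cosen", m=2, r=0.2)
        assert qse == pytest.approx(sa + math.log(2 * r_abs), rel=1e-9)
        assert cos == pytest.approx(qse - math.log(x.mean()), rel=1e-9)

    def test_sampen_nonincreasing_in_r(self, rng):
        x = rng.normal(size=400)
        vals = [regularity_family(x, "sampen", m=2, r=r)
                for r in (0.1, 0.15, 0.2, 0.3, 0.5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_no_matches_returns_nan(self):
        x = np.array([0.0, 100.0, 1.0, 50.0, 7.0, 90.0, 3.0])
        assert math.isnan(regularity_family(x, "sampen", m=2, r=1e-6))

    def test_fuzzy_finite_and_ordered(self, rng):
        x = rng.normal(size=300)
        fz = regularity_family(x, "fuzzy", m=2, r=0.2)
        assert np.isfinite(fz) and fz > 0

    def test_fsampen_envelope_smoother(self, rng):
        x = rng.normal(size=600)
        fs = regularity_family(x, "fsampen", m=2, r=0.2, envelope_window=16)
        sa = regularity_family(x, "sampen", m=2, r=0.2)
        assert np.isfinite(fs)
        assert fs < sa  # the RMS envelope is far more regular


class TestOrdinalFamily:
    def test_monotone_series_zero(self):
        assert ordinal_family(np.arange(50.0), "pe", m=3) == 0.0
        assert ordinal_family(np.arange(50.0), "pme", m=3) == 0.0

    def test_hand_enumeration_m2(self):
        x = np.array([4.0, 7, 9, 10, 6, 11, 3])
        # up/down pattern proportions (4/6, 2/6)
        expected = -(4 / 6 * math.log(4 / 6) + 2 / 6 * math.log(2 / 6)) / math.log(2)
        assert ordinal_family(x, "pe", m=2) == pytest.approx(expected, rel=1e-12)

    def test_pme_bounded_by_pe(self, rng):
        for _ in range(100):
            x = rng.normal(size=200)
            assert ordinal_family(x, "pme", m=3) <= ordinal_family(x, "pe", m=3) + 1e-12

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=300)
        for kind in ("pe", "pme"):
            a = ordinal_family(x, kind, m=3)
            b = ordinal_family(np.exp(x), kind, m=3)
            assert a == pytest.approx(b, rel=1e-12)

    def test_aape_weights_amplitude(self, rng):
        x = rng.normal(size=500)
        v = ordinal_family(x, "aape", m=3)
        assert 0 <= v <= 1


class TestDispersionEntropy:
    def test_constant_class_zero(self):
        x = np.tile([1.0, 1.001], 100)  # all samples land in middle classes
        de, _ = dispersion_entropy(np.linspace(0, 1e-3, 50) + 1.0, m=2, c=2)
        assert de >= 0  # computable; tiny spread still classifies

    def test_iid_near_maximal(self, rng):
        x = rng.uniform(size=100_000)
        _, nde = dispersion_entropy(x, m=2, c=3)
        assert nde > 0.95

    @pytest.mark.parametrize("seed", range(3))
    def test_pattern_census_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        p = dispersion_pattern_probs(x, m=2, c=2, tau=1)
        census = dispersion_census_oracle(x, m=2, c=2, tau=1)
        total = sum(census.values())
        for pat, cnt in census.items():
            code = (pat[0] - 1) + (pat[1] - 1) * 2
            assert p[code] == pytest.approx(cnt / total, abs=1e-15)

    def test_sd_zero_errors(self):
        with pytest.raises(ValueError):
            dispersion_entropy(np.ones(50), m=2, c=3)


class TestBubbleEntropy:
    def test_monotone_series_zero_swaps(self):
        assert bubble_entropy(np.arange(100.0), m=4) == 0.0

    @pytest.mark.parametrize("v, expected", [([3, 1, 2], 2), ([1, 2, 3], 0), ([3, 2, 1], 3)])
    def test_swap_counter_hand_values(self, v, expected):
        assert swap_count(np.array(v)) == expected
        assert swap_count_oracle(v) == expected

    def test_swap_counts_match_inversion_oracle(self, rng):
        from ceps.entropy import _swap_counts_all

        x = rng.normal(size=60)
        counts = _swap_counts_all(x, 5)
        from ceps.embedding import delay_embed

        emb = delay_embed(x, 5, 1)
        expected = [swap_count_oracle(row) for row in emb]
        np.testing.assert_array_equal(counts, expected)

    def test_monotone_transform_invariance(self, rng):
        for _ in range(50):
            x = rng.normal(size=120)
            assert bubble_entropy(x, m=5) == pytest.approx(
                bubble_entropy(x**3, m=5), rel=1e-12
            )


class TestSlopeEntropy:
    def test_constant_and_uniform_ramp_zero(self):
        assert slope_entropy(np.full(20, 3.0), m=2) == 0.0
        ramp = np.arange(20) * 0.5  # slope between delta and gamma
        assert slope_entropy(ramp, m=2, delta=0.001, gamma=1.0) == 0.0

    def test_word_census_matches_enumeration(self, rng):
        x = rng.normal(size=10)
        sym = _slope_symbols(x, 0.001, 1.0)
        words = {}
        for i in range(len(sym) - 1):
            w = (sym[i], sym[i + 1])
            words[w] = words.get(w, 0) + 1
        total = sum(words.values())
        expected = -sum(c / total * math.log(c / total) for c in words.values())
        assert slope_entropy(x, m=2) == pytest.approx(expected, rel=1e-12)

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError):
            slope_entropy(np.arange(10.0), m=2, delta=1.0, gamma=0.5)


class TestDistributionEntropy:
    def test_identical_templates_zero(self):
        # every pairwise template distance identical (all zero)
        x = np.full(60, 3.5)
        assert distribution_entropy(x, m=2, bins=16) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(size=100)
        got = distribution_entropy(x, m=2, bins=64)
        assert got == pytest.approx(disten_oracle(x, 2, 64), abs=1e-12)

    def test_bounded_unit_interval(self, rng):
        for _ in range(100):
            x = rng.normal(size=60)
            assert 0.0 <= distribution_entropy(x, m=2, bins=32) <= 1.0


class TestPhaseEntropy:
    def test_isotropic_differences_near_one(self, rng):
        x = rng.standard_normal(100_000).cumsum()
        assert phase_entropy(x, k_sectors=16) > 0.95

    def test_strict_ramp_single_sector(self):
        assert phase_entropy(np.arange(100.0), k_sectors=16) == 0.0

    def test_sign_reversal_invariance(self, rng):
        x = rng.normal(size=500)
        assert phase_entropy(x, 16) == pytest.approx(phase_entropy(-x, 16), abs=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            phase_entropy(np.full(100, 1.0), 8)


class TestToneEntropy:
    def test_constant_intervals(self):
        r = tone_entropy(np.full(300, 800.0))
        assert r.tone == 0.0 and r.entropy == 0.0

    def test_alternating_hand_value(self):
        x = np.tile([800.0, 1000.0], 151)[:301]  # 150 PI of each sign
        r = tone_entropy(x)
        assert r.tone == pytest.approx(-2.5)
        assert r.entropy == pytest.approx(1.0)  # two equal-mass unit bins

    def test_reliability_flags(self, rng):
        short = 800 + rng.normal(0, 20, 50)
        r = tone_entropy(short)
        assert not r.tone_reliable and r.entropy_reliable
        long = 800 + rng.normal(0, 20, 300)
        assert tone_entropy(long).tone_reliable

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            tone_entropy(np.full(49, 800.0))


class TestEntropyOfEntropy:
    def test_constant_series_zero(self):
        assert entropy_of_entropy(np.full(100, 1.0), 5, 4) == 0.0

    def test_two_state_alternation_ln2(self):
        # windows alternate between two deterministic level patterns
        block_a = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        block_b = np.array([0.0, 10.0, 0.0, 10.0, 0.0])
        x = np.concatenate([block_a, block_b] * 10)
        assert entropy_of_entropy(x, 5, 4) == pytest.approx(math.log(2))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_staged_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)  # 5 windows of 5
        got = entropy_of_entropy(x, 5, 4)
        assert got == pytest.approx(eoe_oracle(x, 5, 4), abs=1e-12)


class TestNormalizedBounds:
    def test_normalized_entropies_unit_interval(self, rng):
        for _ in range(200):
            x = rng.normal(size=int(rng.integers(60, 200)))
            assert 0 <= ordinal_family(x, "pe", m=3) <= 1
            assert 0 <= dispersion_entropy(x, m=2, c=4)[1] <= 1
            assert 0 <= distribution_entropy(x, m=2, bins=16) <= 1
            assert 0 <= phase_entropy(x, 8) <= 1
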