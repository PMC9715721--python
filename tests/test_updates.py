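import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sparsebp import (
    NoiseDraw,
    UpdateConfig,
    UpdateMask,
    apply_masked_binary_update,
    apply_masked_gradient_update,
    apply_noise_update,
    compute_error_signals,
    draw_mask,
    draw_noise,
    forward,
    full_gradient,
    init_params,
    sample_mask,
    sgn,
    update_step,
)
from sparsebp.updates import mask_size


@pytest.fixture
def small_trial():
    """A 3-4-2 net with one forward pass and its error signals."""
    rng = np.random.default_rng(10)
    p = init_params(3, 4, 2, rng)
    x = rng.uniform(0, 1, 3)
    t = np.array([1.0, 0.0])
    cache = forward(p, x)
    sig = compute_error_signals(cache, t, p)
    return p, cache, sig


class TestSgn:
    def test_zero(self):
        assert sgn(0) == 0
        assert sgn(0.0) == 0
        assert sgn(-0.0) == 0

    def test_values(self):
        assert sgn(3.7) == 1
        assert sgn(-0.001) == -1

    @given(st.floats(allow_nan=False, allow_infinity=False))
    @settings(max_examples=100, deadline=None)
    def test_odd(self, x):
        assert sgn(x) == -sgn(-x)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            sgn(float("inf"))


class TestSampleMask:
    def test_q_one_full_set(self):
        idx = sample_mask(10, 1.0, np.random.default_rng(0))
        assert sorted(idx) == list(range(10))

    def test_q_zero_empty(self):
        assert sample_mask(10, 0.0, np.random.default_rng(0)).size == 0

    def test_rejects_bad_q(self):
        with pytest.raises(ValueError):
            sample_mask(10, 1.5, np.random.default_rng(0))

    def test_no_duplicates(self):
        idx = sample_mask(100, 0.37, np.random.default_rng(1))
        assert len(set(idx.tolist())) == idx.size

    @given(st.integers(1, 200), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_cardinality_deterministic(self, n, q):
        size = mask_size(n, q)
        assert size == min(n, int(np.floor(q * n + 0.5)))
        idx = sample_mask(n, q, np.random.default_rng(0))
        assert idx.size == size

    def test_uniform_inclusion_frequency(self):
        # q=0.5, n=10: every index selected with frequency 0.5 +- 0.02
        rng = np.random.default_rng(42)
        counts = np.zeros(10)
        n_draws = 10_000
        for _ in range(n_draws):
            counts[sample_mask(10, 0.5, rng)] += 1
        freq = counts / n_draws
        assert np.all(np.abs(freq - 0.5) < 0.02)


class TestMaskedGradientUpdate:
    def test_empty_mask_no_change(self, small_trial):
        p, cache, sig = small_trial
        g = full_gradient(cache, sig)
        mask = UpdateMask(np.empty(0, dtype=int), np.empty(0, dtype=int))
        out = apply_masked_gradient_update(p, g, mask, 0.1)
        assert np.array_equal(out.w_hi, p.w_hi)
        assert np.array_equal(out.w_oh, p.w_oh)

    def test_full_mask_equals_unrestricted(self, small_trial):
        p, cache, sig = small_trial
        g = full_gradient(cache, sig)
        mask = UpdateMask(np.arange(p.w_hi.size), np.arange(p.w_oh.size))
        out = apply_masked_gradient_update(p, g, mask, 0.05)
        assert np.array_equal(out.w_hi, p.w_hi - 0.05 * g.g_hi)
        assert np.array_equal(out.w_oh, p.w_oh - 0.05 * g.g_oh)

    def test_single_index(self, small_trial):
        p, cache, sig = small_trial
        g = full_gradient(cache, sig)
        mask = UpdateMask(np.array([5]), np.empty(0, dtype=int))
        out = apply_masked_gradient_update(p, g, mask, 0.1)
        assert out.w_hi.flat[5] == p.w_hi.flat[5] - 0.1 * g.g_hi.flat[5]
        changed = out.w_hi.ravel() != p.w_hi.ravel()
        assert np.flatnonzero(changed).tolist() in ([], [5])
        assert np.array_equal(out.w_oh, p.w_oh)

    def test_purity(self, small_trial):
        p, cache, sig = small_trial
        before = p.w_hi.copy()
        g = full_gradient(cache, sig)
        apply_masked_gradient_update(p, g, draw_mask(p, 0.5, np.random.default_rng(0)), 0.1)
        assert np.array_equal(p.w_hi, before)

    def test_out_of_range_index(self, small_trial):
        p, cache, sig = small_trial
        g = full_gradient(cache, sig)
        mask = UpdateMask(np.array([p.w_hi.size]), np.empty(0, dtype=int))
        with pytest.raises(IndexError):
            apply_masked_gradient_update(p, g, mask, 0.1)


class TestBinaryUpdate:
    def test_zero_signals_no_change(self, small_trial):
        p, cache, _ = small_trial
        sig = compute_error_signals(cache, cache.a_out.copy(), p)
        mask = UpdateMask(np.arange(p.w_hi.size), np.arange(p.w_oh.size))
        out = apply_masked_binary_update(p, cache, sig, mask, 0.1)
        assert np.array_equal(out.w_hi, p.w_hi)
        assert np.array_equal(out.w_oh, p.w_oh)

    def test_changes_are_exactly_plus_minus_eps(self, small_trial):
        p, cache, sig = small_trial
        eps = 0.07
        mask = draw_mask(p, 0.6, np.random.default_rng(3))
        out = apply_masked_binary_update(p, cache, sig, mask, eps)
        g = full_gradient(cache, sig)
        expected = p.copy()
        expected.w_oh.flat[mask.idx_oh] -= eps * np.sign(g.g_oh.flat[mask.idx_oh])
        expected.w_hi.flat[mask.idx_hi] -= eps * np.sign(g.g_hi.flat[mask.idx_hi])
        assert np.array_equal(out.w_hi, expected.w_hi)
        assert np.array_equal(out.w_oh, expected.w_oh)

    def test_signs_match_full_gradient(self):
        # hand-sized 2-2-1 net: binary steps move opposite the gradient sign
        rng = np.random.default_rng(11)
        p = init_params(2, 2, 1, rng)
        x = np.array([0.9, 0.2])
        cache = forward(p, x)
        sig = compute_error_signals(cache, np.array([1.0]), p)
        g = full_gradient(cache, sig)
        mask = UpdateMask(np.arange(p.w_hi.size), np.arange(p.w_oh.size))
        out = apply_masked_binary_update(p, cache, sig, mask, 0.1)
        step_sign_hi = np.sign(p.w_hi - out.w_hi)  # +1 where weight decreased
        step_sign_oh = np.sign(p.w_oh - out.w_oh)
        assert np.array_equal(step_sign_hi * 0.1, 0.1 * np.sign(g.g_hi))
        assert np.array_equal(step_sign_oh * 0.1, 0.1 * np.sign(g.g_oh))

    def test_unmasked_untouched(self, small_trial):
        p, cache, sig = small_trial
        mask = UpdateMask(np.array([0, 3]), np.array([1]))
        out = apply_masked_binary_update(p, cache, sig, mask, 0.1)
        untouched_hi = np.setdiff1d(np.arange(p.w_hi.size), mask.idx_hi)
        assert np.array_equal(out.w_hi.flat[untouched_hi], p.w_hi.flat[untouched_hi])


class TestNoiseUpdate:
    def test_empty_draw_no_change(self, small_trial):
        p, _, _ = small_trial
        noise = draw_noise(p, 0.0, np.random.default_rng(0))
        out = apply_noise_update(p, noise, 0.1)
        assert np.array_equal(out.w_hi, p.w_hi)

    def test_full_draw_every_weight_moves_eps(self, small_trial):
        p, _, _ = small_trial
        noise = draw_noise(p, 1.0, np.random.default_rng(1))
        out = apply_noise_update(p, noise, 0.1)
        assert np.allclose(np.abs(out.w_hi - p.w_hi), 0.1)
        assert np.allclose(np.abs(out.w_oh - p.w_oh), 0.1)

    def test_rejects_bad_eta(self, small_trial):
        p, _, _ = small_trial
        noise = NoiseDraw(
            idx_hi=np.array([0]), idx_oh=np.empty(0, dtype=int),
            eta_hi=np.array([2]),
        )
        with pytest.raises(ValueError):
            apply_noise_update(p, noise, 0.1)

    def test_zero_mean_increments(self, small_trial):
        # Monte-Carlo: mean noise increment per weight is 0 +- 3 eps sqrt(p/N)
        p, _, _ = small_trial
        rng = np.random.default_rng(12)
        eps, noise_p, n_draws = 0.1, 0.5, 10_000
        total = np.zeros(p.w_hi.size)
        for _ in range(n_draws):
            noise = draw_noise(p, noise_p, rng)
            inc = np.zeros(p.w_hi.size)
            inc[noise.idx_hi] = -eps * noise.eta_hi
            total += inc
        band = 3 * eps * np.sqrt(noise_p / n_draws)
        assert np.all(np.abs(total / n_draws) < band)


class TestUpdateStep:
    def test_stochastic_q1_equals_full(self, small_trial):
        p, cache, sig = small_trial
        full = update_step(p, cache, sig,
                           UpdateConfig(mode="full", learning_rate=0.1),
                           np.random.default_rng(0))
        stoch = update_step(p, cache, sig,
                            UpdateConfig(mode="stochastic", q=1.0, learning_rate=0.1),
                            np.random.default_rng(99))
        assert np.array_equal(full.w_hi, stoch.w_hi)
        assert np.array_equal(full.w_oh, stoch.w_oh)

    def test_binary_noisy_with_zero_noise_matches_binary(self, small_trial):
        p, cache, sig = small_trial
        a = update_step(p, cache, sig,
                        UpdateConfig(mode="binary", q=0.5, learning_rate=0.1),
                        np.random.default_rng(7))
        b = update_step(p, cache, sig,
                        UpdateConfig(mode="binary_noisy", q=0.5, noise_p=0.0,
                                     learning_rate=0.1),
                        np.random.default_rng(7))
        assert np.array_equal(a.w_hi, b.w_hi)
        assert np.array_equal(a.w_oh, b.w_oh)

    def test_fixed_seed_reproducible(self, small_trial):
        p, cache, sig = small_trial
        cfg = UpdateConfig(mode="binary_noisy", q=0.3, noise_p=0.2, learning_rate=0.1)
        a = update_step(p, cache, sig, cfg, np.random.default_rng(5))
        b = update_step(p, cache, sig, cfg, np.random.default_rng(5))
        assert np.array_equal(a.w_hi, b.w_hi)
        assert np.array_equal(a.w_oh, b.w_oh)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            UpdateConfig(mode="nope")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            UpdateConfig(q=-0.1)
        with pytest.raises(ValueError):
            UpdateConfig(noise_p=1.2)
        with pytest.raises(ValueError):
            UpdateConfig(learning_rate=-0.5)

    def test_masking_unbiased_small(self, small_trial):
        # mean of masked updates converges to q * full update (smoke version;
        # the full 10k-draw check lives in the acceptance suite)
        p, cache, sig = small_trial
        g = full_gradient(cache, sig)
        rng = np.random.default_rng(21)
        q, eps, n_draws = 0.5, 0.1, 2000
        acc = np.zeros(p.w_oh.size)
        for _ in range(n_draws):
            out = update_step(p, cache, sig,
                              UpdateConfig(mode="stochastic", q=q, learning_rate=eps),
                              rng)
            acc += (out.w_oh - p.w_oh).ravel()
        mean = acc / n_draws
        target = -q * eps * g.g_oh.ravel()
        se = eps * np.abs(g.g_oh.ravel()) * np.sqrt(q * (1 - q) / n_draws)
        assert np.all(np.abs(mean - target) <= 3 * se + 1e-12)
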