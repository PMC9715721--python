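"""Weight-update rules: full gradient, stochastic masked, one-bit sign,
and uncorrelated-noise updates.

All rules are pure: they return a fresh :class:`NetworkParams` and leave
their input untouched.  Randomness is injected through an explicit
``numpy.random.Generator``; given the same generator state the draw order
is fixed and documented (output layer before hidden layer, and for noise
the index set before the sign values), so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import ErrorSignals, ForwardCache, Gradients, NetworkParams, full_gradient

__all__ = [
    "MODES",
    "UpdateConfig",
    "UpdateMask",
    "NoiseDraw",
    "sgn",
    "mask_size",
    "sample_mask",
    "draw_mask",
    "draw_noise",
    "apply_masked_gradient_update",
    "apply_masked_binary_update",
    "apply_noise_update",
    "update_step",
]

MODES = ("full", "stochastic", "binary", "binary_noisy")


@dataclass(frozen=True)
class UpdateConfig:
    """Configuration of the per-trial weight update.

    Parameters
    ----------
    mode : {"full", "stochastic", "binary", "binary_noisy"}
        ``full`` is plain online gradient descent; ``stochastic`` applies the
        gradient update to a random fraction ``q`` of the weights per layer;
        ``binary`` moves each selected weight by exactly ``-lr``, 0 or ``+lr``
        according to the sign of its gradient term; ``binary_noisy`` is the
        binary rule followed by a random ±lr kick on a fraction ``noise_p``
        of the weights.
    q : float
        Fraction of weights (per layer) that receive a signal update each
        trial.  Ignored when ``mode="full"``.
    noise_p : float
        Fraction of weights that receive a noise update each trial.  Used
        only when ``mode="binary_noisy"``.
    learning_rate : float
        Step size (>= 0; zero is allowed and leaves weights untouched).
    seed : int
        Seed for all run-level randomness (masks, noise, data order).
    """

    mode: str = "full"
    q: float = 1.0
    noise_p: float = 0.0
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not 0.0 <= self.noise_p <= 1.0:
            raise ValueError(f"noise_p must lie in [0, 1], got {self.noise_p}")
        if not self.learning_rate >= 0.0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")


@dataclass
class UpdateMask:
    """Flat index sets into ``w_hi`` and ``w_oh`` selecting the weights that
    receive a signal update this trial."""

    idx_hi: np.ndarray
    idx_oh: np.ndarray


@dataclass
class NoiseDraw:
    """Flat index sets plus ±1 sign values for the noise update."""

    idx_hi: np.ndarray
    idx_oh: np.ndarray
    eta_hi: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    eta_oh: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))


def sgn(x) -> int:
    """Three-valued sign: 1 if x > 0, 0 if x == 0, -1 if x < 0."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError("sgn: input must be finite")
    if x > 0:
        return 1
    if x < 0:
        return -1
    return 0


def mask_size(n_total: int, q: float) -> int:
    """Number of masked weights: round-half-away-from-zero of ``q * n_total``,
    clamped to ``[0, n_total]``."""
    return min(n_total, int(math.floor(q * n_total + 0.5)))


def sample_mask(n_total: int, q: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``round(q * n_total)`` distinct flat indices uniformly without
    replacement."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if n_total < 0:
        raise ValueError("n_total must be non-negative")
    size = mask_size(n_total, q)
    return rng.choice(n_total, size=size, replace=False)


def draw_mask(params: NetworkParams, q: float, rng: np.random.Generator) -> UpdateMask:
    """Fresh per-trial mask; the output-layer indices are drawn first."""
    idx_oh = sample_mask(params.w_oh.size, q, rng)
    idx_hi = sample_mask(params.w_hi.size, q, rng)
    return UpdateMask(idx_hi=idx_hi, idx_oh=idx_oh)


def draw_noise(params: NetworkParams, noise_p: float, rng: np.random.Generator) -> NoiseDraw:
    """Fresh noise draw: per layer, the index set first, then the ±1 values.

    Output layer before hidden layer, matching :func:`draw_mask`.
    """
    idx_oh = sample_mask(params.w_oh.size, noise_p, rng)
    eta_oh = rng.integers(0, 2, size=idx_oh.size) * 2 - 1
    idx_hi = sample_mask(params.w_hi.size, noise_p, rng)
    eta_hi = rng.integers(0, 2, size=idx_hi.size) * 2 - 1
    return NoiseDraw(idx_hi=idx_hi, idx_oh=idx_oh, eta_hi=eta_hi, eta_oh=eta_oh)


def _check_mask(idx: np.ndarray, n_total: int) -> None:
    if idx.size and (idx.min() < 0 or idx.max() >= n_total):
        raise IndexError("mask index out of range")


def apply_masked_gradient_update(
    params: NetworkParams,
    grads: Gradients,
    mask: UpdateMask,
    learning_rate: float,
) -> NetworkParams:
    """``w <- w - lr * g`` at the masked indices only."""
    if grads.g_hi.shape != params.w_hi.shape or grads.g_oh.shape != params.w_oh.shape:
        raise ValueError("gradient shapes do not match parameter shapes")
    _check_mask(mask.idx_hi, params.w_hi.size)
    _check_mask(mask.idx_oh, params.w_oh.size)
    out = params.copy()
    out.w_oh.flat[mask.idx_oh] -= learning_rate * grads.g_oh.flat[mask.idx_oh]
    out.w_hi.flat[mask.idx_hi] -= learning_rate * grads.g_hi.flat[mask.idx_hi]
    return out


def apply_masked_binary_update(
    params: NetworkParams,
    cache: ForwardCache,
    signals: ErrorSignals,
    mask: UpdateMask,
    learning_rate: float,
) -> NetworkParams:
    """One-bit update: each masked weight moves by exactly ``-lr``, 0 or
    ``+lr`` according to the sign of its gradient term.

    The hidden-layer sign argument
    ``(sum_l delta_out_l * w_oh[l,k]) * a_h_k (1 - a_h_k) * a_in_j``
    equals the full-gradient entry ``delta_hidden_k * a_in_j``, so the signs
    are taken from :func:`full_gradient` evaluated with the pre-update
    output weights of the current trial.
    """
    if signals.delta_out.shape[0] != params.n_output:
        raise ValueError("error-signal shape does not match network")
    if signals.delta_hidden.shape[0] != params.n_hidden:
        raise ValueError("error-signal shape does not match network")
    _check_mask(mask.idx_hi, params.w_hi.size)
    _check_mask(mask.idx_oh, params.w_oh.size)
    grads = full_gradient(cache, signals)
    out = params.copy()
    out.w_oh.flat[mask.idx_oh] -= learning_rate * np.sign(grads.g_oh.flat[mask.idx_oh])
    out.w_hi.flat[mask.idx_hi] -= learning_rate * np.sign(grads.g_hi.flat[mask.idx_hi])
    return out


def apply_noise_update(
    params: NetworkParams, noise: NoiseDraw, learning_rate: float
) -> NetworkParams:
    """``w <- w - lr * eta`` (eta = ±1) at the noise-selected indices."""
    for eta in (noise.eta_hi, noise.eta_oh):
        if eta.size and not np.all(np.abs(eta) == 1):
            raise ValueError("noise values must be ±1")
    if noise.eta_hi.size != noise.idx_hi.size or noise.eta_oh.size != noise.idx_oh.size:
        raise ValueError("noise index/value lengths differ")
    _check_mask(noise.idx_hi, params.w_hi.size)
    _check_mask(noise.idx_oh, params.w_oh.size)
    out = params.copy()
    out.w_oh.flat[noise.idx_oh] -= learning_rate * noise.eta_oh
    out.w_hi.flat[noise.idx_hi] -= learning_rate * noise.eta_hi
    return out


def update_step(
    params: NetworkParams,
    cache: ForwardCache,
    signals: ErrorSignals,
    config: UpdateConfig,
    rng: np.random.Generator,
) -> NetworkParams:
    """Dispatch one weight update according to ``config.mode``.

    ``full`` consumes no randomness.  Masked modes draw one fresh mask per
    trial; ``binary_noisy`` additionally draws an independent noise set after
    the signal update (skipped entirely when ``noise_p == 0`` so that the
    generator stream matches plain ``binary`` mode).  Overlapping signal and
    noise indices receive both increments sequentially.
    """
    lr = config.learning_rate
    if config.mode == "full":
        grads = full_gradient(cache, signals)
        out = params.copy()
        out.w_oh -= lr * grads.g_oh
        out.w_hi -= lr * grads.g_hi
        return out
    if config.mode == "stochastic":
        mask = draw_mask(params, config.q, rng)
        grads = full_gradient(cache, signals)
        return apply_masked_gradient_update(params, grads, mask, lr)
    if config.mode == "binary":
        mask = draw_mask(params, config.q, rng)
        return apply_masked_binary_update(params, cache, signals, mask, lr)
    if config.mode == "binary_noisy":
        mask = draw_mask(params, config.q, rng)
        out = apply_masked_binary_update(params, cache, signals, mask, lr)
        if config.noise_p > 0.0:
            noise = draw_noise(params, config.noise_p, rng)
            out = apply_noise_update(out, noise, lr)
        return out
    raise ValueError(f"unknown mode {config.mode!r}")
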