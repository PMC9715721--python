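"""Three-layer logistic network: forward pass, loss, error signals, gradients.

The network is input -> hidden -> output with logistic units in the hidden
and output layers.  The hidden bias is stored as the last column of the
hidden-from-input weight matrix, acting on a constant input of 1, so it is
trained (and masked) exactly like every other hidden-layer weight.  The
output layer has no bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParams",
    "ForwardCache",
    "ErrorSignals",
    "Gradients",
    "logistic",
    "logistic_slope",
    "forward",
    "forward_batch",
    "squared_error_loss",
    "compute_error_signals",
    "full_gradient",
    "init_params",
    "save_params",
    "load_params",
]


def logistic(x):
    """Numerically stable logistic function ``1 / (1 + exp(-x))``.

    Accepts scalars or arrays; never overflows, even for ``|x| >> 700``.

    Raises
    ------
    ValueError
        If any input value is not finite.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("logistic: input must be finite")
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-arr[pos]))
    ex = np.exp(arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def logistic_slope(a):
    """Derivative of the logistic w.r.t. its pre-activation, evaluated from
    the stored activation value as ``a * (1 - a)``.

    Raises
    ------
    ValueError
        If ``a`` is not strictly inside (0, 1).
    """
    arr = np.asarray(a, dtype=float)
    if not np.all((arr > 0.0) & (arr < 1.0)):
        raise ValueError("logistic_slope: activation must lie strictly in (0, 1)")
    out = arr * (1.0 - arr)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class NetworkParams:
    """Weights of the 3-layer network.

    Attributes
    ----------
    w_hi : (n_hidden, n_input + 1) array
        Hidden-from-input weights; the final column is the hidden bias,
        applied against a constant input of 1.
    w_oh : (n_output, n_hidden) array
        Output-from-hidden weights.  No output bias.
    """

    w_hi: np.ndarray
    w_oh: np.ndarray

    def __post_init__(self) -> None:
        self.w_hi = np.asarray(self.w_hi, dtype=float)
        self.w_oh = np.asarray(self.w_oh, dtype=float)
        if self.w_hi.ndim != 2 or self.w_oh.ndim != 2:
            raise ValueError("weight matrices must be 2-D")
        if self.w_hi.shape[1] < 2:
            raise ValueError("w_hi must have at least one input column plus the bias column")
        if self.w_oh.shape[1] != self.w_hi.shape[0]:
            raise ValueError(
                f"inconsistent shapes: w_oh has {self.w_oh.shape[1]} hidden columns "
                f"but w_hi has {self.w_hi.shape[0]} hidden rows"
            )
        if not (np.all(np.isfinite(self.w_hi)) and np.all(np.isfinite(self.w_oh))):
            raise ValueError("weights must be finite")

    @property
    def n_input(self) -> int:
        return self.w_hi.shape[1] - 1

    @property
    def n_hidden(self) -> int:
        return self.w_hi.shape[0]

    @property
    def n_output(self) -> int:
        return self.w_oh.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.w_hi.copy(), self.w_oh.copy())


@dataclass
class ForwardCache:
    """Activations from one forward pass.

    ``a_in`` is the input augmented with a trailing constant 1 (the bias
    input), ``a_hidden`` and ``a_out`` are the logistic activations.
    """

    a_in: np.ndarray
    a_hidden: np.ndarray
    a_out: np.ndarray


@dataclass
class ErrorSignals:
    """Output-layer and hidden-layer teaching signals for one trial."""

    delta_out: np.ndarray
    delta_hidden: np.ndarray


@dataclass
class Gradients:
    """Exact loss gradients, shaped like the corresponding weight matrices."""

    g_hi: np.ndarray
    g_oh: np.ndarray


def forward(params: NetworkParams, x) -> ForwardCache:
    """Run one input through the network and cache all activations."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != params.n_input:
        raise ValueError(
            f"input must be a vector of length {params.n_input}, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    a_in = np.append(x, 1.0)
    a_hidden = logistic(params.w_hi @ a_in)
    a_out = logistic(params.w_oh @ a_hidden)
    return ForwardCache(a_in=a_in, a_hidden=a_hidden, a_out=a_out)


def forward_batch(params: NetworkParams, inputs: np.ndarray) -> np.ndarray:
    """Vectorised forward pass; returns the (n, n_output) output activations."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 2 or inputs.shape[1] != params.n_input:
        raise ValueError(
            f"inputs must have shape (n, {params.n_input}), got {inputs.shape}"
        )
    ones = np.ones((inputs.shape[0], 1))
    a_in = np.hstack([inputs, ones])
    a_hidden = logistic(a_in @ params.w_hi.T)
    return logistic(a_hidden @ params.w_oh.T)


def squared_error_loss(output, target) -> float:
    """Half the summed squared residual between output and target."""
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    if not (np.all(np.isfinite(output)) and np.all(np.isfinite(target))):
        raise ValueError("loss arguments must be finite")
    diff = output - target
    return 0.5 * float(diff @ diff)


def compute_error_signals(cache: ForwardCache, target, params: NetworkParams) -> ErrorSignals:
    """Backpropagate the output residual into per-unit error signals.

    ``delta_out = a_out - target``;
    ``delta_hidden_k = (sum_l delta_out_l * w_oh[l, k]) * a_h_k * (1 - a_h_k)``.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != cache.a_out.shape:
        raise ValueError(
            f"target shape {target.shape} does not match output shape {cache.a_out.shape}"
        )
    delta_out = cache.a_out - target
    slope = cache.a_hidden * (1.0 - cache.a_hidden)
    delta_hidden = (params.w_oh.T @ delta_out) * slope
    return ErrorSignals(delta_out=delta_out, delta_hidden=delta_hidden)


def full_gradient(cache: ForwardCache, signals: ErrorSignals) -> Gradients:
    """Exact gradient of the squared-error loss for one trial.

    Each layer gradient is the outer product of its error signal with the
    upstream activations (the bias column receives ``delta_hidden * 1``).
    """
    g_oh = np.outer(signals.delta_out, cache.a_hidden)
    g_hi = np.outer(signals.delta_hidden, cache.a_in)
    return Gradients(g_hi=g_hi, g_oh=g_oh)


def init_params(
    n_input: int, n_hidden: int, n_output: int, rng: np.random.Generator
) -> NetworkParams:
    """Seeded uniform initialisation on (-r, r), r = sqrt(6 / (fan_in + fan_out)).

    Keeps logistic units away from saturation at the start of training.
    """
    if min(n_input, n_hidden, n_output) < 1:
        raise ValueError("all layer sizes must be >= 1")
    r_hi = np.sqrt(6.0 / (n_input + 1 + n_hidden))
    r_oh = np.sqrt(6.0 / (n_hidden + n_output))
    w_hi = rng.uniform(-r_hi, r_hi, size=(n_hidden, n_input + 1))
    w_oh = rng.uniform(-r_oh, r_oh, size=(n_output, n_hidden))
    return NetworkParams(w_hi=w_hi, w_oh=w_oh)


def save_params(params: NetworkParams, path) -> None:
    """Write the weight matrices to an ``.npz`` checkpoint."""
    np.savez(path, w_hi=params.w_hi, w_oh=params.w_oh)


def load_params(path) -> NetworkParams:
    """Load a checkpoint written by :func:`save_params`."""
    with np.load(path) as f:
        return NetworkParams(w_hi=f["w_hi"], w_oh=f["w_oh"])
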