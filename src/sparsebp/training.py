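"""Online training loop with per-trial errors, a moving-average error rate,
periodic validation and test-set evaluation.

Randomness contract: the run seed (``UpdateConfig.seed``) is split into two
independent streams — one for the example order (reshuffled every epoch) and
one for the update rule's mask/noise draws.  ``full`` mode consumes nothing
from the update stream, so a ``stochastic`` run with ``q=1`` replays the
identical trajectory.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset
from .network import NetworkParams, compute_error_signals, forward, forward_batch
from .updates import UpdateConfig, update_step

__all__ = [
    "TrainingSchedule",
    "TrainingLog",
    "trial_error",
    "moving_average_error",
    "train_online",
    "evaluate_misclassification",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """How long to train, how often to validate, and the moving-window length."""

    n_trials: int
    validation_every: int = 500
    moving_window: int = 100

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.validation_every < 1 or self.moving_window < 1:
            raise ValueError("schedule fields must be positive")
        if self.validation_every > self.n_trials:
            raise ValueError("validation_every must not exceed n_trials")


@dataclass
class TrainingLog:
    """Per-trial results of one training run."""

    trial_errors: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))
    error_rate_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    validation_points: list[tuple[int, float]] = field(default_factory=list)
    final_test_error: float | None = None

    def to_csv(self, curve_path, validation_path) -> None:
        with open(curve_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "trial_error", "error_rate"])
            for n, (e, r) in enumerate(
                zip(self.trial_errors, self.error_rate_curve), start=1
            ):
                w.writerow([n, int(e), f"{r:.6f}"])
        with open(validation_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "validation_error"])
            for n, v in self.validation_points:
                w.writerow([n, f"{v:.6f}"])

    def summary(self) -> dict:
        out = {
            "n_trials": int(self.trial_errors.shape[0]),
            "final_error_rate": float(self.error_rate_curve[-1])
            if self.error_rate_curve.size
            else None,
            "final_test_error": self.final_test_error,
        }
        if self.validation_points:
            out["final_validation_error"] = float(self.validation_points[-1][1])
        return out

    def save_summary(self, path, extra: dict | None = None) -> None:
        payload = self.summary()
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def trial_error(output, target) -> int:
    """0 if the network's arg-max class matches the one-hot target, else 1."""
    output = np.asarray(output, dtype=float)
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    return int(output.argmax() != target.argmax())


def moving_average_error(errors, window: int) -> float:
    """Mean of the last ``min(window, len(errors))`` trial errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("errors must be non-empty")
    if window < 1:
        raise ValueError("window must be positive")
    return float(errors[-window:].mean())


def evaluate_misclassification(params: NetworkParams, data: LabeledDataset) -> float:
    """Fraction of examples whose arg-max output misses the target class.

    Pure evaluation; no weights change.
    """
    if len(data) == 0:
        raise ValueError("dataset must be non-empty")
    outputs = forward_batch(params, data.inputs)
    return float(np.mean(outputs.argmax(axis=1) != data.labels))


def train_online(
    params0: NetworkParams,
    train_data: LabeledDataset,
    val_data: LabeledDataset | None,
    config: UpdateConfig,
    schedule: TrainingSchedule,
) -> tuple[NetworkParams, TrainingLog]:
    """Train one example at a time for ``schedule.n_trials`` trials.

    Each trial: draw the next example (epoch-wise shuffling), forward pass,
    record the 0/1 trial error, compute error signals, apply one update per
    ``config``.  Every ``schedule.validation_every`` trials the
    misclassification rate on ``val_data`` (if given) is appended to the log.
    """
    if len(train_data) == 0:
        raise ValueError("training data must be non-empty")
    if train_data.n_features != params0.n_input:
        raise ValueError(
            f"data has {train_data.n_features} features but network expects "
            f"{params0.n_input}"
        )
    if train_data.n_classes != params0.n_output:
        raise ValueError(
            f"data has {train_data.n_classes} classes but network has "
            f"{params0.n_output} outputs"
        )

    ss = np.random.SeedSequence(config.seed)
    data_ss, update_ss = ss.spawn(2)
    data_rng = np.random.default_rng(data_ss)
    update_rng = np.random.default_rng(update_ss)

    params = params0.copy()
    m = len(train_data)
    n_trials = schedule.n_trials
    window = schedule.moving_window

    errors = np.zeros(n_trials, dtype=np.uint8)
    curve = np.zeros(n_trials)
    validation_points: list[tuple[int, float]] = []
    order = data_rng.permutation(m)
    pos = 0
    window_sum = 0

    for n in range(n_trials):
        if pos == m:  # epoch boundary: reshuffle and continue
            order = data_rng.permutation(m)
            pos = 0
        i = order[pos]
        pos += 1

        cache = forward(params, train_data.inputs[i])
        target = train_data.targets[i]
        e = trial_error(cache.a_out, target)
        errors[n] = e
        window_sum += e
        if n >= window:
            window_sum -= errors[n - window]
        curve[n] = window_sum / min(n + 1, window)

        signals = compute_error_signals(cache, target, params)
        params = update_step(params, cache, signals, config, update_rng)

        if val_data is not None and (n + 1) % schedule.validation_every == 0:
            validation_points.append(
                (n + 1, evaluate_misclassification(params, val_data))
            )

    log = TrainingLog(
        trial_errors=errors,
        error_rate_curve=curve,
        validation_points=validation_points,
    )
    return params, log
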