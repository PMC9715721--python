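"""Sweep runner: (q, learning-rate) grids, hidden-size comparisons, and
noise curves, each repeated over several independently seeded networks.

Seeding: every repetition's seed is derived from
``SeedSequence([master_seed, i_hidden, i_q, i_eps, i_noise, rep])``, so a
sweep is bit-reproducible and cells can be recomputed in isolation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .data import LabeledDataset, SyntheticTaskSpec, generate_dataset, split_train_validation
from .network import init_params
from .training import TrainingSchedule, evaluate_misclassification, train_online
from .updates import MODES, UpdateConfig

__all__ = [
    "SweepSpec",
    "CellResult",
    "SweepResult",
    "make_datasets",
    "run_repetition",
    "run_grid_sweep",
    "run_size_comparison",
    "run_noise_curves",
]


@dataclass
class SweepSpec:
    """Grid definition plus the base training setup shared by all cells."""

    dataset: SyntheticTaskSpec
    mode: str = "binary"
    q_values: Sequence[float] = (0.1,)
    epsilon_values: Sequence[float] = (0.1,)
    noise_values: Sequence[float] = ()
    hidden_sizes: Sequence[int] = (64,)
    n_repetitions: int = 10
    n_trials: int = 20000
    validation_every: int = 500
    moving_window: int = 100
    n_validation: int = 500
    n_test: int = 1000
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if not self.q_values or not self.epsilon_values or not self.hidden_sizes:
            raise ValueError("grids must be non-empty")

    def schedule(self) -> TrainingSchedule:
        return TrainingSchedule(
            n_trials=self.n_trials,
            validation_every=self.validation_every,
            moving_window=self.moving_window,
        )


@dataclass
class CellResult:
    """Per-cell aggregate: repetition-level test errors plus their mean/std."""

    q: float
    epsilon: float
    noise_p: float
    hidden: int
    test_errors: list[float]
    final_error_rates: list[float]
    curves: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_test_error(self) -> float:
        return float(np.mean(self.test_errors))

    @property
    def std_test_error(self) -> float:
        return float(np.std(self.test_errors))


@dataclass
class SweepResult:
    cells: list[CellResult]
    master_seed: int

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["q", "epsilon", "noise_p", "hidden", "mean_test_error", "std_test_error"]
            )
            for c in self.cells:
                w.writerow(
                    [c.q, c.epsilon, c.noise_p, c.hidden,
                     f"{c.mean_test_error:.6f}", f"{c.std_test_error:.6f}"]
                )

    def save_summary(self, path, spec: SweepSpec | None = None) -> None:
        payload = {
            "master_seed": self.master_seed,
            "cells": [
                {
                    "q": c.q,
                    "epsilon": c.epsilon,
                    "noise_p": c.noise_p,
                    "hidden": c.hidden,
                    "mean_test_error": c.mean_test_error,
                    "std_test_error": c.std_test_error,
                    "test_errors": c.test_errors,
                    "final_error_rates": c.final_error_rates,
                }
                for c in self.cells
            ],
        }
        if spec is not None:
            payload["spec"] = asdict(spec)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def make_datasets(spec: SweepSpec) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Build the (train, validation, test) triple for a sweep.

    The test set is generated from an independent stream of the dataset seed
    so it never overlaps the training pool.
    """
    base_ss = np.random.SeedSequence(spec.dataset.seed)
    train_ss, test_ss, split_ss = base_ss.spawn(3)
    pool = generate_dataset(spec.dataset, np.random.default_rng(train_ss))
    if not 0 < spec.n_validation < len(pool):
        raise ValueError("n_validation must be smaller than the generated pool")
    train, val = split_train_validation(
        pool, spec.n_validation, np.random.default_rng(split_ss)
    )
    test_task = SyntheticTaskSpec(**{**asdict(spec.dataset), "n_examples": spec.n_test})
    test = generate_dataset(test_task, np.random.default_rng(test_ss))
    return train, val, test


def run_repetition(
    spec: SweepSpec,
    datasets: tuple[LabeledDataset, LabeledDataset, LabeledDataset],
    hidden: int,
    q: float,
    epsilon: float,
    noise_p: float,
    seed_key: Sequence[int],
):
    """Train one network for one grid cell; returns (test_error, log)."""
    train, val, test = datasets
    ss = np.random.SeedSequence(list(seed_key))
    init_state, train_state = ss.generate_state(2)
    params0 = init_params(
        train.n_features, hidden, train.n_classes, np.random.default_rng(int(init_state))
    )
    config = UpdateConfig(
        mode=spec.mode, q=q, noise_p=noise_p,
        learning_rate=epsilon, seed=int(train_state),
    )
    params, log = train_online(params0, train, val, config, spec.schedule())
    log.final_test_error = evaluate_misclassification(params, test)
    return log.final_test_error, log


def _run_cells(spec: SweepSpec, cells_spec, keep_curves: bool) -> SweepResult:
    datasets = make_datasets(spec)
    cells: list[CellResult] = []
    for (ih, hidden), (iq, q), (ie, eps), (inp, noise_p) in cells_spec:
        test_errors, final_rates, curves = [], [], []
        for rep in range(spec.n_repetitions):
            seed_key = (spec.master_seed, ih, iq, ie, inp, rep)
            err, log = run_repetition(spec, datasets, hidden, q, eps, noise_p, seed_key)
            test_errors.append(err)
            final_rates.append(float(log.error_rate_curve[-1]))
            if keep_curves:
                curves.append(log.error_rate_curve)
        cells.append(
            CellResult(
                q=q, epsilon=eps, noise_p=noise_p, hidden=hidden,
                test_errors=test_errors, final_error_rates=final_rates, curves=curves,
            )
        )
    return SweepResult(cells=cells, master_seed=spec.master_seed)


def run_grid_sweep(spec: SweepSpec, keep_curves: bool = False) -> SweepResult:
    """Full (q, epsilon[, noise_p]) grid at the first hidden size."""
    hidden = spec.hidden_sizes[0]
    noise_grid = (
        list(enumerate(spec.noise_values))
        if spec.mode == "binary_noisy" and spec.noise_values
        else [(0, 0.0)]
    )
    cells_spec = [
        ((0, hidden), (iq, q), (ie, e), (inp, npv))
        for iq, q in enumerate(spec.q_values)
        for ie, e in enumerate(spec.epsilon_values)
        for inp, npv in noise_grid
    ]
    return _run_cells(spec, cells_spec, keep_curves)


def run_size_comparison(spec: SweepSpec, keep_curves: bool = True) -> SweepResult:
    """One cell per hidden size at the first (q, epsilon); curves retained."""
    q = spec.q_values[0]
    eps = spec.epsilon_values[0]
    noise_p = spec.noise_values[0] if (spec.mode == "binary_noisy" and spec.noise_values) else 0.0
    cells_spec = [
        ((ih, h), (0, q), (0, eps), (0, noise_p))
        for ih, h in enumerate(spec.hidden_sizes)
    ]
    return _run_cells(spec, cells_spec, keep_curves)


def run_noise_curves(spec: SweepSpec, keep_curves: bool = True) -> SweepResult:
    """One cell per noise level at fixed (q, epsilon); requires binary_noisy."""
    if spec.mode != "binary_noisy":
        raise ValueError("run_noise_curves requires mode='binary_noisy'")
    if not spec.noise_values:
        raise ValueError("noise_values must be non-empty")
    hidden = spec.hidden_sizes[0]
    q = spec.q_values[0]
    eps = spec.epsilon_values[0]
    cells_spec = [
        ((0, hidden), (0, q), (0, eps), (inp, npv))
        for inp, npv in enumerate(spec.noise_values)
    ]
    return _run_cells(spec, cells_spec, keep_curves)
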