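"""Shared helpers for the test suite: seeded training runs and datasets."""

from __future__ import annotations

import numpy as np

from sparsebp import (
    SyntheticTaskSpec,
    TrainingSchedule,
    UpdateConfig,
    generate_dataset,
    init_params,
    train_online,
)


def make_glyphs(n_classes=10, n_examples=6000, noise_sd=0.1, max_shift=1, seed=11):
    return generate_dataset(
        SyntheticTaskSpec(
            kind="glyphs", n_classes=n_classes, n_examples=n_examples,
            noise_sd=noise_sd, max_shift=max_shift, seed=seed,
        )
    )


def make_blobs(n_classes=3, n_features=16, n_examples=3000, noise_sd=0.15, seed=900):
    return generate_dataset(
        SyntheticTaskSpec(
            kind="blobs", n_classes=n_classes, n_features=n_features,
            n_examples=n_examples, noise_sd=noise_sd, seed=seed,
        )
    )


def train_run(
    data,
    hidden,
    mode,
    q,
    eps,
    n_trials,
    seed,
    noise_p=0.0,
    val_data=None,
    validation_every=None,
):
    """Init (seeded) + train; returns (params0, params, log)."""
    params0 = init_params(
        data.n_features, hidden, data.n_classes, np.random.default_rng(seed + 500)
    )
    config = UpdateConfig(
        mode=mode, q=q, noise_p=noise_p, learning_rate=eps, seed=seed
    )
    schedule = TrainingSchedule(
        n_trials=n_trials,
        validation_every=validation_every or n_trials,
    )
    params, log = train_online(params0, data, val_data, config, schedule)
    return params0, params, log
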