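# sparsebp

Online training of a 3-layer logistic network (input → hidden → output,
squared-error objective, one example per trial) under four weight-update
rules:

- **full** — plain online gradient descent;
- **stochastic** — each trial, only a random fraction `q` of the weights in
  each layer receives the gradient update;
- **binary** — each selected weight moves by exactly `−ε`, `0` or `+ε`
  according to the three-valued sign of its gradient term (one bit of
  backward information per weight);
- **binary_noisy** — the binary rule followed by an uncorrelated `±ε` kick
  on a random fraction `noise_p` of the weights.

The hidden bias is stored as the last column of the hidden weight matrix
(against a constant input of 1), so it is trained and masked like any other
weight. The output layer has no bias. The per-trial error is the 0/1
arg-max mismatch; the reported error rate is its moving average over the
last 100 trials, with validation every 500 trials.

The package ships seeded synthetic tasks (Gaussian class blobs and noisy
low-resolution digit glyphs) so every experiment and test runs without
downloads, plus readers for MNIST-style IDX files if you supply them.

## CLI

```bash
# single run on the built-in glyph task
sparsebp train --mode binary --q 0.1 --epsilon 0.1 --hidden 64 \
    --trials 20000 --seed 0 --data glyphs --out run_out

# MNIST-style IDX input
sparsebp train --data idx:train-images-idx3-ubyte,train-labels-idx1-ubyte \
    --mode stochastic --q 0.1 --epsilon 0.01 --hidden 500 --trials 60000

# parameter sweep from a YAML spec (see tests/test_cli.py for the schema)
sparsebp sweep --config sweep.yaml --kind grid --out sweep_out

# synthetic data export (CSV, optionally IDX)
sparsebp gen-data --kind glyphs --n 1000 --out glyphs --idx

# evaluate a checkpoint
sparsebp eval --checkpoint run_out/checkpoint.npz --data glyphs
```

`train` writes `curve.csv` (trial, trial_error, error_rate),
`validation.csv`, `summary.json` and `checkpoint.npz`. `sweep` writes
`cells.csv` (q, epsilon, noise_p, hidden, mean/std test error) and a JSON
summary with per-repetition values. All randomness — initialisation, data
order, masks, noise — derives from the run seed; sweep repetitions fan out
from the master seed, so every number is bit-reproducible.

## Library layout

| module | contents |
| --- | --- |
| `sparsebp.network` | forward pass, loss, error signals, exact gradients |
| `sparsebp.updates` | masks, sign/noise draws, the four update rules |
| `sparsebp.training` | online loop, moving-average error, validation/test evaluation |
| `sparsebp.data` | IDX reader/writer, blob and glyph generators, splits |
| `sparsebp.experiments` | grid sweeps, hidden-size comparisons, noise curves |
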