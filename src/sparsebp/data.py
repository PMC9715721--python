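"""Datasets: IDX-format readers/writers and seeded synthetic generators.

Two synthetic tasks make the whole system testable without downloads:

* ``blobs`` — Gaussian clouds around class centres drawn on the unit sphere,
  affinely squashed into [0, 1]; linearly separable for small noise.
* ``glyphs`` — low-resolution digit images built from fixed 5x5 bitmap
  templates for the digits 0-9, with per-pixel Gaussian noise and random
  1-pixel translations; a miniature stand-in for a 10-class image task.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabeledDataset",
    "SyntheticTaskSpec",
    "IdxFormatError",
    "read_idx",
    "write_idx",
    "load_digit_dataset",
    "one_hot",
    "generate_blobs",
    "generate_glyphs",
    "generate_dataset",
    "split_train_validation",
    "GLYPH_TEMPLATES",
]

_IDX_UBYTE = 0x08


class IdxFormatError(ValueError):
    """Raised for malformed IDX files; messages name the failing byte offset."""


@dataclass
class LabeledDataset:
    """A classification dataset: inputs in [0, 1], one-hot targets.

    ``inputs`` has shape (m, n_features), ``targets`` shape (m, n_classes).
    """

    inputs: np.ndarray
    targets: np.ndarray
    n_classes: int

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.ndim != 2 or self.targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D")
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError(
                f"{self.inputs.shape[0]} inputs but {self.targets.shape[0]} targets"
            )
        if self.targets.shape[1] != self.n_classes:
            raise ValueError("target width does not match n_classes")
        if self.inputs.size and (self.inputs.min() < 0.0 or self.inputs.max() > 1.0):
            raise ValueError("input values must lie in [0, 1]")
        if self.targets.size:
            ok = np.all(np.isin(self.targets, (0.0, 1.0))) and np.all(
                self.targets.sum(axis=1) == 1.0
            )
            if not ok:
                raise ValueError("targets must be one-hot")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_features(self) -> int:
        return self.inputs.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.targets.argmax(axis=1)

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.inputs[idx], self.targets[idx], self.n_classes)

    def to_csv(self, path) -> None:
        """One row per example: features then the integer label."""
        m = np.column_stack([self.inputs, self.labels.astype(float)])
        header = ",".join(
            [f"x{j}" for j in range(self.n_features)] + ["label"]
        )
        np.savetxt(path, m, delimiter=",", header=header, comments="")


@dataclass
class SyntheticTaskSpec:
    """Parameters of a synthetic task.

    ``kind`` is ``"blobs"`` (uses ``n_features``) or ``"glyphs"`` (uses
    ``glyph_size``; inputs are flattened ``glyph_size**2`` images).
    ``max_shift`` (glyphs only) bounds the random per-example translation in
    pixels; 0 disables translation.
    """

    kind: str = "glyphs"
    n_classes: int = 10
    n_features: int = 16
    glyph_size: int = 8
    n_examples: int = 1000
    noise_sd: float = 0.1
    max_shift: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("blobs", "glyphs"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if min(self.n_classes, self.n_features, self.n_examples) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")


def read_idx(path) -> np.ndarray:
    """Decode a big-endian IDX file of unsigned bytes into an integer tensor."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 4:
        raise IdxFormatError(f"{path}: truncated header at offset {len(raw)}")
    zero0, zero1, dtype, ndim = raw[0], raw[1], raw[2], raw[3]
    if zero0 != 0 or zero1 != 0:
        raise IdxFormatError(f"{path}: bad magic at offset 0 (first two bytes must be 0)")
    if dtype != _IDX_UBYTE:
        raise IdxFormatError(
            f"{path}: unsupported dtype code 0x{dtype:02x} at offset 2 (only ubyte 0x08)"
        )
    if ndim < 1:
        raise IdxFormatError(f"{path}: zero dimensions declared at offset 3")
    header_end = 4 + 4 * ndim
    if len(raw) < header_end:
        raise IdxFormatError(f"{path}: truncated dimension list at offset {len(raw)}")
    dims = struct.unpack(f">{ndim}I", raw[4:header_end])
    n_items = int(np.prod([int(d) for d in dims], dtype=np.int64))
    if len(raw) - header_end < n_items:
        raise IdxFormatError(
            f"{path}: header declares {n_items} bytes of data but only "
            f"{len(raw) - header_end} present after offset {header_end}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=header_end, count=n_items)
    return data.reshape(dims).astype(np.int64)


def write_idx(path, tensor) -> None:
    """Write an integer tensor (values 0-255) as a big-endian ubyte IDX file."""
    arr = np.asarray(tensor)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("IDX ubyte values must lie in 0..255")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, _IDX_UBYTE, arr.ndim))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.astype(np.uint8).tobytes())


def one_hot(label: int, n_classes: int) -> np.ndarray:
    """Length-``n_classes`` vector with a single 1 at ``label``."""
    label = int(label)
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} out of range for {n_classes} classes")
    v = np.zeros(n_classes)
    v[label] = 1.0
    return v


def load_digit_dataset(images_path, labels_path, n_classes: int = 10) -> LabeledDataset:
    """Load an IDX image/label pair: pixels scaled by 1/255, row-major
    flattening, labels one-hot over ``n_classes``."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim < 2:
        raise IdxFormatError(f"{images_path}: expected >= 2 dimensions for images")
    if labels.ndim != 1:
        raise IdxFormatError(f"{labels_path}: expected 1 dimension for labels")
    if images.shape[0] != labels.shape[0]:
        raise IdxFormatError(
            f"count mismatch: {images.shape[0]} images vs {labels.shape[0]} labels"
        )
    inputs = images.reshape(images.shape[0], -1).astype(float) / 255.0
    targets = np.zeros((labels.shape[0], n_classes))
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise IdxFormatError(f"{labels_path}: label outside 0..{n_classes - 1}")
    targets[np.arange(labels.shape[0]), labels] = 1.0
    return LabeledDataset(inputs=inputs, targets=targets, n_classes=n_classes)


def _balanced_labels(n_examples: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    labels = np.arange(n_examples) % n_classes
    return labels[rng.permutation(n_examples)]


def generate_blobs(spec: SyntheticTaskSpec, rng: np.random.Generator) -> LabeledDataset:
    """Gaussian class blobs with centres on the unit sphere, mapped into [0, 1].

    Points are squashed by the fixed affine map ``x -> (x + 1) / 2`` (centres
    land in [0, 1] exactly); noise tails outside the cube are clipped.
    """
    if spec.kind != "blobs":
        raise ValueError("spec.kind must be 'blobs'")
    centers = rng.standard_normal((spec.n_classes, spec.n_features))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    labels = _balanced_labels(spec.n_examples, spec.n_classes, rng)
    points = centers[labels] + spec.noise_sd * rng.standard_normal(
        (spec.n_examples, spec.n_features)
    )
    inputs = np.clip((points + 1.0) / 2.0, 0.0, 1.0)
    targets = np.zeros((spec.n_examples, spec.n_classes))
    targets[np.arange(spec.n_examples), labels] = 1.0
    return LabeledDataset(inputs=inputs, targets=targets, n_classes=spec.n_classes)


# 5x5 bitmap templates for the digits 0-9; rows are strings of 0/1.
_GLYPH_ROWS = {
    0: ("01110", "10001", "10001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00110", "01000", "11111"),
    3: ("11110", "00001", "00110", "00001", "11110"),
    4: ("10010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "11110"),
    6: ("01110", "10000", "11110", "10001", "01110"),
    7: ("11111", "00010", "00100", "01000", "01000"),
    8: ("01110", "10001", "01110", "10001", "01110"),
    9: ("01110", "10001", "01111", "00001", "01110"),
}

GLYPH_TEMPLATES: dict[int, np.ndarray] = {
    d: np.array([[float(c) for c in row] for row in rows])
    for d, rows in _GLYPH_ROWS.items()
}
_TEMPLATE_SIZE = 5


def render_glyph(
    digit: int, glyph_size: int, shift: tuple[int, int] = (0, 0)
) -> np.ndarray:
    """Noise-free ``glyph_size`` x ``glyph_size`` image of one digit template,
    centred then shifted by ``shift`` (clamped so the template stays inside)."""
    if glyph_size < _TEMPLATE_SIZE:
        raise ValueError(f"glyph_size must be >= {_TEMPLATE_SIZE}")
    template = GLYPH_TEMPLATES[int(digit)]
    base = (glyph_size - _TEMPLATE_SIZE) // 2
    hi = glyph_size - _TEMPLATE_SIZE
    r = min(max(base + shift[0], 0), hi)
    c = min(max(base + shift[1], 0), hi)
    canvas = np.zeros((glyph_size, glyph_size))
    canvas[r : r + _TEMPLATE_SIZE, c : c + _TEMPLATE_SIZE] = template
    return canvas


def generate_glyphs(spec: SyntheticTaskSpec, rng: np.random.Generator) -> LabeledDataset:
    """Noisy, translated digit glyphs flattened to ``glyph_size**2`` features."""
    if spec.kind != "glyphs":
        raise ValueError("spec.kind must be 'glyphs'")
    if spec.glyph_size < _TEMPLATE_SIZE:
        raise ValueError(f"glyph_size must be >= {_TEMPLATE_SIZE}")
    if spec.n_classes > 10:
        raise ValueError("glyph task supports at most 10 classes")
    g = spec.glyph_size
    labels = _balanced_labels(spec.n_examples, spec.n_classes, rng)
    inputs = np.empty((spec.n_examples, g * g))
    s = spec.max_shift
    for i, lab in enumerate(labels):
        shift = (int(rng.integers(-s, s + 1)), int(rng.integers(-s, s + 1))) if s else (0, 0)
        img = render_glyph(int(lab), g, shift)
        if spec.noise_sd > 0:
            img = img + spec.noise_sd * rng.standard_normal((g, g))
        inputs[i] = np.clip(img, 0.0, 1.0).ravel()
    targets = np.zeros((spec.n_examples, spec.n_classes))
    targets[np.arange(spec.n_examples), labels] = 1.0
    return LabeledDataset(inputs=inputs, targets=targets, n_classes=spec.n_classes)


def generate_dataset(spec: SyntheticTaskSpec, rng: np.random.Generator | None = None) -> LabeledDataset:
    """Dispatch on ``spec.kind``; builds a generator from ``spec.seed`` when
    none is supplied."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.kind == "blobs":
        return generate_blobs(spec, rng)
    return generate_glyphs(spec, rng)


def split_train_validation(
    data: LabeledDataset, n_validation: int, rng: np.random.Generator
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint seeded random split into (train, validation)."""
    m = len(data)
    if not 0 < n_validation < m:
        raise ValueError(f"n_validation must lie in (0, {m}), got {n_validation}")
    perm = rng.permutation(m)
    val_idx = perm[:n_validation]
    train_idx = perm[n_validation:]
    return data.subset(train_idx), data.subset(val_idx)
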