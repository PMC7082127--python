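"""Random classification problems, synthetic digit images, and IDX file I/O.

The perceptron experiments use dense random binary patterns: each of the P
patterns is a vector of N independent ±1 entries plus an always-on bias
input, associated with an independent binary target.  The multilayer
experiments use either user-supplied MNIST-format IDX files or a synthetic
digit-like generator (fixed class prototypes plus pixel noise) that needs no
external data.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatternSet",
    "LabeledImageSet",
    "IdxFormatError",
    "generate_pattern_set",
    "generate_synthetic_digits",
    "read_idx",
    "write_idx",
    "save_pattern_set",
    "load_pattern_set",
]

_IDX_IMAGE_MAGIC = 0x00000803
_IDX_LABEL_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """Raised when an IDX file violates the format contract."""


@dataclass(frozen=True)
class PatternSet:
    """P binary input patterns over N synapses plus a bias unit.

    ``inputs`` is a P×(N+1) float matrix whose non-bias entries are ±1 and
    whose final column is the constant +1 bias input; ``targets`` holds the
    desired binary outputs in {0, 1}.
    """

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.ascontiguousarray(np.asarray(self.inputs, dtype=np.float64))
        targets = np.asarray(self.targets)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", np.ascontiguousarray(targets.astype(np.int64)))
        if inputs.ndim != 2 or inputs.shape[0] < 1 or inputs.shape[1] < 2:
            raise ValueError("inputs must be a P x (N+1) matrix with P >= 1, N >= 1")
        if not np.all(np.abs(inputs[:, :-1]) == 1.0):
            raise ValueError("non-bias inputs must be exactly -1 or +1")
        if not np.all(inputs[:, -1] == 1.0):
            raise ValueError("bias column must be all +1")
        if self.targets.shape != (inputs.shape[0],):
            raise ValueError("targets must be a length-P vector")
        if not np.isin(self.targets, (0, 1)).all():
            raise ValueError("targets must contain only 0 and 1")

    @property
    def n_patterns(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_synapses(self) -> int:
        """Number of plastic synapses excluding the bias weight."""
        return self.inputs.shape[1] - 1

    @property
    def n_weights(self) -> int:
        """Number of trainable weights including the bias weight (N+1)."""
        return self.inputs.shape[1]


@dataclass(frozen=True)
class LabeledImageSet:
    """Flattened grey-scale images in [0, 1] with class labels in {0..9}."""

    images: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        images = np.ascontiguousarray(np.asarray(self.images, dtype=np.float64))
        labels = np.ascontiguousarray(np.asarray(self.labels, dtype=np.int64))
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "labels", labels)
        if images.ndim != 2:
            raise ValueError("images must be an n x d matrix")
        if labels.shape != (images.shape[0],):
            raise ValueError("image count must equal label count")
        if images.size and (images.min() < 0.0 or images.max() > 1.0):
            raise ValueError("pixel values must lie in [0, 1]")
        if labels.size and (labels.min() < 0 or labels.max() > 9):
            raise ValueError("labels must be class indices in {0..9}")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.images.shape[1]


def generate_pattern_set(n_synapses: int, n_patterns: int, seed: int) -> PatternSet:
    """Draw a random binary classification problem.

    Inputs are i.i.d. uniform on {−1, +1} with a final always-on bias column;
    targets are i.i.d. uniform on {0, 1}.  The same seed reproduces the same
    set bit-for-bit.
    """
    if n_synapses < 1 or n_patterns < 1:
        raise ValueError("n_synapses and n_patterns must be positive")
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n_patterns, n_synapses)).astype(np.float64) * 2.0 - 1.0
    inputs = np.hstack([x, np.ones((n_patterns, 1))])
    targets = rng.integers(0, 2, size=n_patterns)
    return PatternSet(inputs=inputs, targets=targets)


def generate_synthetic_digits(
    n_classes: int = 10,
    n_per_class: int = 100,
    side: int = 8,
    noise_sd: float = 0.2,
    seed: int = 0,
    prototype_seed: int | None = None,
) -> LabeledImageSet:
    """Digit-like images: one random prototype per class plus pixel noise.

    Each class has a fixed prototype drawn uniformly from [0, 1]^(side²);
    samples are the prototype plus i.i.d. Gaussian noise, clipped back to
    [0, 1].  Classes are exactly balanced.  ``prototype_seed`` (default:
    ``seed``) fixes the prototypes independently of the sample noise, so a
    held-out set is drawn with the same ``prototype_seed`` but a different
    ``seed``.
    """
    if not 1 <= n_classes <= 10:
        raise ValueError("n_classes must be between 1 and 10")
    if n_per_class < 1 or side < 1:
        raise ValueError("n_per_class and side must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = side * side
    prototypes = class_prototypes(n_classes, side, seed if prototype_seed is None else prototype_seed)
    images = np.repeat(prototypes, n_per_class, axis=0)
    if noise_sd > 0:
        images = images + rng.normal(0.0, noise_sd, size=images.shape)
        images = np.clip(images, 0.0, 1.0)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return LabeledImageSet(images=images, labels=labels)


def class_prototypes(n_classes: int = 10, side: int = 8, seed: int = 0) -> np.ndarray:
    """The noise-free prototypes used by :func:`generate_synthetic_digits`."""
    rng = np.random.default_rng(seed)
    return rng.random((n_classes, side * side))


def _read_header(data: bytes, path, expected_magic: int, n_dims: int) -> tuple[tuple[int, ...], int]:
    header_len = 4 * (1 + n_dims)
    if len(data) < header_len:
        raise IdxFormatError(f"{path}: truncated IDX header")
    magic = struct.unpack(">i", data[:4])[0]
    if magic != expected_magic:
        raise IdxFormatError(
            f"{path}: bad IDX magic number 0x{magic:08x}, expected 0x{expected_magic:08x}"
        )
    dims = struct.unpack(f">{n_dims}i", data[4:header_len])
    return dims, header_len


def read_idx(images_path, labels_path) -> LabeledImageSet:
    """Read an MNIST-style IDX image/label file pair.

    Pixel bytes are scaled to [0, 1] by division by 255 and images flattened
    row-major.  Magic-number mismatches, image/label count mismatches and
    truncated payloads are reported as distinct :class:`IdxFormatError`s.
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    img_data = images_path.read_bytes()
    lab_data = labels_path.read_bytes()
    (n_img, rows, cols), img_off = _read_header(img_data, images_path, _IDX_IMAGE_MAGIC, 3)
    (n_lab,), lab_off = _read_header(lab_data, labels_path, _IDX_LABEL_MAGIC, 1)
    if n_img != n_lab:
        raise IdxFormatError(
            f"image count {n_img} ({images_path}) does not match label count {n_lab} ({labels_path})"
        )
    n_pix = rows * cols
    if len(img_data) - img_off < n_img * n_pix:
        raise IdxFormatError(f"{images_path}: truncated pixel payload")
    if len(lab_data) - lab_off < n_lab:
        raise IdxFormatError(f"{labels_path}: truncated label payload")
    pixels = np.frombuffer(img_data, dtype=np.uint8, count=n_img * n_pix, offset=img_off)
    labels = np.frombuffer(lab_data, dtype=np.uint8, count=n_lab, offset=lab_off)
    images = pixels.reshape(n_img, n_pix).astype(np.float64) / 255.0
    return LabeledImageSet(images=images, labels=labels.astype(np.int64))


def write_idx(dataset: LabeledImageSet, images_path, labels_path, side: int | None = None) -> None:
    """Write a :class:`LabeledImageSet` as a big-endian IDX file pair."""
    n, d = dataset.images.shape
    if side is None:
        side = int(round(np.sqrt(d)))
    if side * side != d:
        raise ValueError("images are not square; pass side explicitly")
    pixels = np.round(dataset.images * 255.0).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGE_MAGIC, n, side, side))
        fh.write(pixels.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABEL_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


def save_pattern_set(patterns: PatternSet, path) -> None:
    """Save a pattern set as a gzipped CSV reproducibility bundle.

    Columns ``x0..x{N-1}`` hold the ±1 inputs (bias column omitted, it is
    always +1) and ``target`` the binary outputs.
    """
    n = patterns.n_synapses
    df = pd.DataFrame(patterns.inputs[:, :-1].astype(np.int64), columns=[f"x{i}" for i in range(n)])
    df["target"] = patterns.targets
    df.to_csv(path, index=False, compression="gzip")


def load_pattern_set(path) -> PatternSet:
    """Inverse of :func:`save_pattern_set`."""
    with gzip.open(path, "rt") as fh:
        df = pd.read_csv(fh)
    targets = df.pop("target").to_numpy()
    x = df.to_numpy(dtype=np.float64)
    inputs = np.hstack([x, np.ones((x.shape[0], 1))])
    return PatternSet(inputs=inputs, targets=targets)
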