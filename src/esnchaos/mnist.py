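"""Optional MNIST loader (IDX format, plain or gzip-compressed).

MNIST is an *external* input: nothing in the package downloads it, and no
test depends on it.  Users who have the four standard IDX files
(train-images-idx3-ubyte[.gz], train-labels-idx1-ubyte[.gz],
t10k-images-idx3-ubyte[.gz], t10k-labels-idx1-ubyte[.gz]) can load them
into an :class:`~esnchaos.images.ImageSet` for the full-scale
classification profile.
"""

from __future__ import annotations

import gzip
import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .images import ImageSet

__all__ = ["read_idx", "load_mnist"]

_IDX_DTYPES = {
    0x08: np.uint8,
    0x09: np.int8,
    0x0B: ">i2",
    0x0C: ">i4",
    0x0D: ">f4",
    0x0E: ">f8",
}


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_idx(path) -> np.ndarray:
    """Read one IDX-format array (gzip detected automatically)."""
    path = Path(path)
    with _open_maybe_gzip(path) as fh:
        zero, dtype_code, ndim = struct.unpack(">HBB", fh.read(4))
        if zero != 0 or dtype_code not in _IDX_DTYPES:
            raise ValueError(f"{path} is not an IDX file")
        shape = struct.unpack(f">{ndim}I", fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=_IDX_DTYPES[dtype_code])
    return data.reshape(shape)


def _find(directory: Path, stem: str) -> Path:
    for suffix in ("", ".gz"):
        candidate = directory / f"{stem}{suffix}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def load_mnist(
    directory, kind: str = "train", limit: Optional[int] = None, seed: int = 0
) -> ImageSet:
    """Load MNIST images + labels as an ImageSet (pixels scaled to [0, 1]).

    ``kind`` is "train" or "t10k"; ``limit`` optionally subsamples that
    many images uniformly at random (the full-scale profile trains on
    20,000 of the 60,000 training images).
    """
    if kind not in ("train", "t10k"):
        raise ValueError("kind must be 'train' or 't10k'")
    directory = Path(directory)
    images = read_idx(_find(directory, f"{kind}-images-idx3-ubyte")).astype(float) / 255.0
    labels = read_idx(_find(directory, f"{kind}-labels-idx1-ubyte")).astype(int)
    if limit is not None and limit < len(images):
        idx = np.sort(
            np.random.default_rng(seed).choice(len(images), size=limit, replace=False)
        )
        images, labels = images[idx], labels[idx]
    return ImageSet(images, labels=labels, seed=seed, generator=f"mnist-{kind}")
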