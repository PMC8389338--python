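"""Synthetic image ensembles with controlled statistical structure.

Three generators produce the stimulus classes used throughout the package:

* :func:`generate_lowrank_images` — images confined to an exactly
  d-dimensional linear subspace (smooth random basis x Gaussian latents),
  emulating reduced-rank stimuli with a known embedding dimension.
* :func:`generate_naturalistic_images` — high-dimensional images with an
  isotropic power-law spatial spectrum ~ f^(-beta) and random phases,
  emulating the second-order statistics of natural scenes.
* :func:`generate_labeled_images` — a multi-class set built from distinct
  oriented-grating templates plus pixel noise, for classification tasks.

Images are H x W grayscale matrices with values in [0, 1].  For the echo
state network they are read column by column (left to right), so an image
becomes a multivariate time series of W steps with H features per step
(:func:`image_to_sequence`).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional

import h5py
import numpy as np
from PIL import Image
from scipy import ndimage

from .exceptions import (
    DimensionError,
    InsufficientSamplesError,
    InvalidClassCountError,
    NormalizationError,
)

__all__ = [
    "ImageSet",
    "InputSequence",
    "generate_lowrank_images",
    "generate_naturalistic_images",
    "generate_labeled_images",
    "class_templates",
    "image_to_sequence",
    "sequence_to_image",
    "radial_power_spectrum",
    "save_png",
    "load_png",
    "save_image_set",
    "load_image_set",
]


@dataclasses.dataclass
class ImageSet:
    """An ordered ensemble of same-shape grayscale images in [0, 1].

    Attributes
    ----------
    images : ndarray, shape (M, H, W)
        Pixel values in [0, 1].
    labels : ndarray of int, optional
        One class label per image, in [0, F); every class occurs at least
        once.
    intrinsic_dim : int, optional
        Known embedding dimension d of the ensemble (low-rank generator).
    seed : int
        Seed the ensemble was generated from.
    generator : str
        Name of the generator that produced the ensemble.
    """

    images: np.ndarray
    labels: Optional[np.ndarray] = None
    intrinsic_dim: Optional[int] = None
    seed: int = 0
    generator: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise DimensionError(
                f"images must be a (M, H, W) array, got shape {self.images.shape}"
            )
        if self.images.size == 0:
            raise DimensionError("empty image set")
        lo, hi = float(self.images.min()), float(self.images.max())
        if lo < 0.0 or hi > 1.0:
            raise NormalizationError(
                f"pixel values must lie in [0, 1], found range [{lo}, {hi}]"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.n_images,):
                raise DimensionError("labels must be one integer per image")
            n_classes = int(self.labels.max()) + 1
            present = np.unique(self.labels)
            if self.labels.min() < 0 or len(present) != n_classes:
                raise InvalidClassCountError(
                    "labels must cover every class in [0, F) at least once"
                )
        if self.intrinsic_dim is not None and self.intrinsic_dim < 1:
            raise DimensionError("intrinsic_dim must be a positive integer")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def height(self) -> int:
        return self.images.shape[1]

    @property
    def width(self) -> int:
        return self.images.shape[2]

    @property
    def n_classes(self) -> Optional[int]:
        if self.labels is None:
            return None
        return int(self.labels.max()) + 1

    def __len__(self) -> int:
        return self.n_images

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.images)

    def flattened(self) -> np.ndarray:
        """Images flattened row-major to a (M, H*W) matrix."""
        return self.images.reshape(self.n_images, -1)

    def subset(self, indices) -> "ImageSet":
        """A new ImageSet restricted to ``indices`` (labels preserved)."""
        idx = np.asarray(indices)
        labels = None if self.labels is None else self.labels[idx]
        return ImageSet(
            self.images[idx],
            labels=labels,
            intrinsic_dim=self.intrinsic_dim,
            seed=self.seed,
            generator=self.generator,
        )


@dataclasses.dataclass
class InputSequence:
    """A multivariate time series derived from one image.

    ``steps[t]`` is column t of the source image: T = W steps, each a
    length-H vector of values in [0, 1].
    """

    steps: np.ndarray  # (T, L1)
    source_image_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 2:
            raise DimensionError("steps must be a (T, L1) array")

    @property
    def n_steps(self) -> int:
        return self.steps.shape[0]

    @property
    def n_features(self) -> int:
        return self.steps.shape[1]

    def __len__(self) -> int:
        return self.n_steps


def _check_positive_dims(n_images: int, height: int, width: int) -> None:
    if height < 1 or width < 1:
        raise DimensionError(f"image dimensions must be positive, got {height}x{width}")
    if n_images < 1:
        raise InsufficientSamplesError("n_images must be >= 1")


def generate_lowrank_images(
    n_images: int,
    height: int,
    width: int,
    d: int,
    smoothness: Optional[float] = None,
    seed: int = 0,
) -> ImageSet:
    """Images confined to an exactly d-dimensional linear subspace.

    Each flattened image is a linear combination of ``d`` fixed,
    spatially-smooth, mutually orthonormal basis patterns with i.i.d.
    standard-normal latent coordinates; the whole ensemble is then mapped
    affinely (global min/max) into [0, 1].  The affine map preserves the
    rank of the mean-centered ensemble, so the returned images still span
    a subspace of dimension exactly ``d``.

    Parameters
    ----------
    d : int
        Embedding dimension, 1 <= d <= height*width; n_images must exceed d.
    smoothness : float, optional
        Gaussian smoothing length-scale (pixels) of the basis patterns.
        Defaults to max(height, width)/6.
    """
    _check_positive_dims(n_images, height, width)
    if d < 1 or d > height * width:
        raise DimensionError(
            f"intrinsic dimension d={d} must satisfy 1 <= d <= {height * width}"
        )
    if n_images <= d:
        raise InsufficientSamplesError(
            f"need n_images > d to span a d-dimensional ensemble (got {n_images} <= {d})"
        )
    rng = np.random.default_rng(seed)
    if smoothness is None:
        smoothness = max(height, width) / 6.0
    fields = rng.standard_normal((d, height, width))
    if smoothness > 0:
        fields = ndimage.gaussian_filter(fields, sigma=(0, smoothness, smoothness))
    # orthonormalise the smooth patterns so the subspace dimension is exact
    q, _ = np.linalg.qr(fields.reshape(d, -1).T)
    basis = q.T  # (d, H*W), orthonormal rows
    latents = rng.standard_normal((n_images, d))
    flat = latents @ basis
    lo, hi = flat.min(), flat.max()
    if hi <= lo:  # pragma: no cover - measure-zero degeneracy
        raise DegenerateEnsembleError("constant ensemble; use another seed")
    images = ((flat - lo) / (hi - lo)).reshape(n_images, height, width)
    return ImageSet(images, intrinsic_dim=d, seed=seed, generator="lowrank")


class DegenerateEnsembleError(RuntimeError):
    """All generated pixels identical (cannot rescale to [0, 1])."""


def generate_naturalistic_images(
    n_images: int,
    height: int,
    width: int,
    spectral_slope: float = 2.0,
    seed: int = 0,
    normalize: str = "per-image",
) -> ImageSet:
    """High-dimensional images with a power-law spatial power spectrum.

    Each image is a Gaussian random field whose isotropic power spectrum
    scales as f^(-spectral_slope) with independent random phases (the DC
    component is removed).  ``spectral_slope=0`` gives white noise;
    ``spectral_slope=2`` approximates the second-order statistics of
    natural scenes.

    Parameters
    ----------
    normalize : {"per-image", "ensemble"}
        Whether the affine [0, 1] rescale uses each image's own min/max
        (default) or the global ensemble min/max.
    """
    _check_positive_dims(n_images, height, width)
    if spectral_slope < 0:
        raise ValueError("spectral_slope must be >= 0")
    if normalize not in ("per-image", "ensemble"):
        raise ValueError("normalize must be 'per-image' or 'ensemble'")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(height)[:, None]
    fx = np.fft.fftfreq(width)[None, :]
    f = np.hypot(fy, fx)
    amplitude = np.zeros_like(f)
    nz = f > 0
    amplitude[nz] = f[nz] ** (-spectral_slope / 2.0)
    noise = rng.standard_normal((n_images, height, width))
    fields = np.fft.ifft2(np.fft.fft2(noise) * amplitude).real
    if normalize == "per-image":
        lo = fields.min(axis=(1, 2), keepdims=True)
        hi = fields.max(axis=(1, 2), keepdims=True)
    else:
        lo = fields.min()
        hi = fields.max()
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    images = (fields - lo) / span
    return ImageSet(images, seed=seed, generator="naturalistic")


def class_templates(n_classes: int, height: int, width: int) -> np.ndarray:
    """Deterministic, well-separated smooth templates, one per class.

    Each class is an elongated Gaussian blob on a dark background: class c
    is centered at angle 2*pi*c/F on a circle around the image center and
    oriented at angle pi*c/F.  Like handwritten-digit images, most pixels
    are near zero, so the input drive to a reservoir is spatially sparse.
    Values lie in [0, 0.85].
    """
    if n_classes < 2:
        raise InvalidClassCountError("need at least 2 classes")
    yy, xx = np.meshgrid(
        np.linspace(-0.5, 0.5, height), np.linspace(-0.5, 0.5, width), indexing="ij"
    )
    templates = np.empty((n_classes, height, width))
    for c in range(n_classes):
        phi = 2.0 * np.pi * c / n_classes
        cy, cx = 0.22 * np.sin(phi), 0.22 * np.cos(phi)
        theta = np.pi * c / n_classes
        # coordinates along / across the blob's major axis
        u = np.cos(theta) * (xx - cx) + np.sin(theta) * (yy - cy)
        v = -np.sin(theta) * (xx - cx) + np.cos(theta) * (yy - cy)
        templates[c] = 0.85 * np.exp(-(u / 0.30) ** 2 - (v / 0.09) ** 2)
    return templates


def generate_labeled_images(
    n_per_class: int,
    n_classes: int,
    height: int,
    width: int,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ImageSet:
    """A labeled multi-class image set: class template + pixel noise.

    Each image is its class template plus i.i.d. zero-mean Gaussian pixel
    noise of standard deviation ``noise_sd``, clipped to [0, 1].  Exactly
    ``n_per_class`` images per class, ordered class-major.
    """
    _check_positive_dims(n_per_class, height, width)
    if n_classes < 2:
        raise InvalidClassCountError(f"need at least 2 classes, got {n_classes}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    templates = class_templates(n_classes, height, width)
    images = np.repeat(templates, n_per_class, axis=0)
    if noise_sd > 0:
        images = images + noise_sd * rng.standard_normal(images.shape)
    images = np.clip(images, 0.0, 1.0)
    labels = np.repeat(np.arange(n_classes), n_per_class)
    return ImageSet(images, labels=labels, seed=seed, generator="labeled")


def image_to_sequence(image: np.ndarray, source_image_index: Optional[int] = None) -> InputSequence:
    """Read an H x W image as a time series: step t is column t.

    Columns are scanned left to right; row 0 is the top pixel row.  Values
    must already lie in [0, 1]; no transformation is applied.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {image.shape}")
    if image.min() < 0.0 or image.max() > 1.0:
        raise NormalizationError("image values must lie in [0, 1]")
    return InputSequence(steps=image.T.copy(), source_image_index=source_image_index)


def sequence_to_image(sequence: InputSequence) -> np.ndarray:
    """Inverse of :func:`image_to_sequence` (exact round trip)."""
    return sequence.steps.T.copy()


def radial_power_spectrum(images: np.ndarray, n_bins: int = 20):
    """Radially averaged spatial power spectrum of an image ensemble.

    Returns ``(freqs, power)``: mean radial frequency and mean power per
    logarithmic bin, averaged over all images, DC excluded.  Useful for
    verifying the spectral slope of generated ensembles.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    m, h, w = images.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx).ravel()
    power = (np.abs(np.fft.fft2(images)) ** 2).mean(axis=0).ravel()
    nz = f > 0
    f, power = f[nz], power[nz]
    edges = np.logspace(np.log10(f.min()), np.log10(f.max()), n_bins + 1)
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            freqs.append(f[sel].mean())
            means.append(power[sel].mean())
    return np.asarray(freqs), np.asarray(means)


# ---------------------------------------------------------------------------
# File I/O: 8-bit grayscale PNG for single images, HDF5 for ensembles.
# ---------------------------------------------------------------------------

def save_png(image: np.ndarray, path) -> None:
    """Write one [0,1] image as 8-bit grayscale PNG, v -> round(255*v)."""
    image = np.asarray(image, dtype=float)
    if image.min() < 0.0 or image.max() > 1.0:
        raise NormalizationError("image values must lie in [0, 1]")
    arr = np.round(255.0 * image).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back to a float image in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def save_image_set(image_set: ImageSet, path) -> None:
    """Persist an ensemble to HDF5 (/images, /labels, generator metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=image_set.images)
        if image_set.labels is not None:
            f.create_dataset("labels", data=image_set.labels)
        f.attrs["seed"] = image_set.seed
        f.attrs["generator"] = image_set.generator
        f.attrs["intrinsic_dim"] = (
            -1 if image_set.intrinsic_dim is None else image_set.intrinsic_dim
        )


def load_image_set(path) -> ImageSet:
    """Load an ensemble written by :func:`save_image_set` (full precision)."""
    with h5py.File(path, "r") as f:
        images = f["images"][...]
        labels = f["labels"][...] if "labels" in f else None
        d = int(f.attrs.get("intrinsic_dim", -1))
        return ImageSet(
            images,
            labels=labels,
            intrinsic_dim=None if d < 0 else d,
            seed=int(f.attrs.get("seed", 0)),
            generator=str(f.attrs.get("generator", "")),
        )
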