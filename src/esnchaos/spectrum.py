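"""Covariance eigenspectra, power-law decay exponents, and cvPCA.

The central quantity is the rank-ordered eigenspectrum of the unit-by-unit
covariance of reservoir activity (units are variables, time-stimulus
samples are observations).  Its decay is modeled as a power law of the
rank, variance_n ~ n^(-alpha).  The exponent alpha is compared with the
continuity + differentiability bound

    alpha_c = 1 + 2/d

for inputs embedded in d dimensions (alpha_c -> 1 as d -> infinity): a
representation manifold can be continuous and differentiable only if
alpha > alpha_c, continuous but not differentiable if 1 < alpha < alpha_c,
and neither if alpha < 1.

Cross-validated PCA (:func:`cvpca`) estimates the stimulus-related
("signal") component variances from two repeats that share the signal but
carry independent noise: eigenvectors are taken from repeat 1 and the
variance of repeat 2 confined to each of them is measured, which cancels
noise variance in expectation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .exceptions import DimensionError, FitError, InsufficientSamplesError

__all__ = [
    "EigenSpectrum",
    "PowerLawFit",
    "CvPCAResult",
    "ManifoldClass",
    "compute_eigenspectrum",
    "fit_powerlaw",
    "powerlaw_ml_exponent",
    "cvpca",
    "cplusd_threshold",
    "classify_manifold",
    "CPLUSD",
    "CONTINUOUS_NOT_DIFFERENTIABLE",
    "NEITHER",
]

LOGLOG = "loglog-regression"
CLAUSET = "clauset-ml"

CPLUSD = "C+D"
CONTINUOUS_NOT_DIFFERENTIABLE = "continuous-not-differentiable"
NEITHER = "neither"


@dataclasses.dataclass
class EigenSpectrum:
    """Rank-ordered (descending) principal-component variances."""

    variances: np.ndarray
    total_variance: float

    @property
    def n_components(self) -> int:
        return len(self.variances)

    def rank(self) -> np.ndarray:
        """1-based ranks matching ``variances``."""
        return np.arange(1, self.n_components + 1)


@dataclasses.dataclass
class PowerLawFit:
    """Fitted decay exponent of a rank-ordered spectrum."""

    alpha: float
    method: str
    rank_range: Tuple[int, int]
    goodness: float  # R^2 (regression) or KS statistic (clauset-ml)
    stderr: float
    n_used: int


@dataclasses.dataclass
class CvPCAResult:
    """Signal variances per component; negatives are retained, not clipped."""

    signal_variances: np.ndarray
    basis: str = "repeat1"

    @property
    def n_components(self) -> int:
        return len(self.signal_variances)


@dataclasses.dataclass
class ManifoldClass:
    """Continuity/differentiability class of a representation manifold."""

    label: str  # CPLUSD | CONTINUOUS_NOT_DIFFERENTIABLE | NEITHER
    boundary: bool  # True when alpha sits exactly on a class boundary
    alpha: float
    threshold: float  # 1 + 2/d


def compute_eigenspectrum(activity: np.ndarray) -> EigenSpectrum:
    """PCA eigenspectrum of an N x S activity matrix.

    Each unit (row) is mean-centered across all S samples; the eigenvalues
    of the resulting covariance (normalized by S) are returned sorted in
    descending order.  Negative numerical dust below 1e-12 of the total is
    clipped to zero.
    """
    activity = np.asarray(activity, dtype=float)
    if activity.ndim != 2:
        raise DimensionError("activity must be an N x S matrix")
    n_samples = activity.shape[1]
    if n_samples < 2:
        raise InsufficientSamplesError("need at least 2 samples (columns)")
    centered = activity - activity.mean(axis=1, keepdims=True)
    cov = (centered @ centered.T) / n_samples
    eigenvalues = np.linalg.eigvalsh(cov)[::-1].copy()
    total = float(np.trace(cov))
    dust = np.abs(eigenvalues) < 1e-12 * max(total, np.finfo(float).tiny)
    eigenvalues[dust & (eigenvalues < 0)] = 0.0
    return EigenSpectrum(variances=eigenvalues, total_variance=total)


def _spectrum_values(spectrum) -> np.ndarray:
    if isinstance(spectrum, EigenSpectrum):
        return spectrum.variances
    if isinstance(spectrum, CvPCAResult):
        return spectrum.signal_variances
    return np.asarray(spectrum, dtype=float)


def fit_powerlaw(
    spectrum: Union[EigenSpectrum, CvPCAResult, np.ndarray],
    method: str = LOGLOG,
    rank_range: Optional[Tuple[int, int]] = None,
) -> PowerLawFit:
    """Fit variance_n ~ n^(-alpha) over a rank range.

    ``loglog-regression`` (default): least-squares slope of log variance
    vs log rank; alpha = -slope, goodness = R^2.

    ``clauset-ml``: the Clauset-style continuous-power-law ML estimator
    with KS-minimizing lower cutoff, applied to the eigenvalue *values*.
    For a rank law v_n ~ n^(-alpha) the value distribution has CCDF
    ~ v^(-1/alpha), so the ML value-exponent a maps to the rank-decay
    exponent as alpha = 1/(a - 1); that converted alpha is reported, with
    the KS statistic as goodness.

    The default range is [11, min(500, n_components)].  Nonpositive
    variances inside the range truncate it (with a warning); fewer than 10
    usable ranks raise :class:`FitError`.
    """
    values = _spectrum_values(spectrum)
    n = len(values)
    if rank_range is None:
        rank_range = (11, min(500, n))
    n_min, n_max = int(rank_range[0]), int(rank_range[1])
    if not (1 <= n_min <= n_max <= n):
        raise FitError(
            f"rank_range {rank_range} invalid for a spectrum of {n} components"
        )
    ranks = np.arange(n_min, n_max + 1)
    vals = values[n_min - 1 : n_max]
    nonpos = vals <= 0
    if nonpos.any():
        cut = int(np.argmax(nonpos))  # rank-ordered: keep the positive prefix
        warnings.warn(
            f"truncating power-law fit range at rank {n_min + cut - 1}: "
            "nonpositive variances inside range",
            stacklevel=2,
        )
        ranks, vals = ranks[:cut], vals[:cut]
    if len(vals) < 10:
        raise FitError("fewer than 10 usable ranks with positive variance")
    if method == LOGLOG:
        res = stats.linregress(np.log(ranks), np.log(vals))
        return PowerLawFit(
            alpha=-float(res.slope),
            method=LOGLOG,
            rank_range=(n_min, int(ranks[-1])),
            goodness=float(res.rvalue**2),
            stderr=float(res.stderr),
            n_used=len(vals),
        )
    if method == CLAUSET:
        a, _, ks, m = powerlaw_ml_exponent(vals, xmin="scan")
        if a <= 1.0 + 1e-9:
            raise FitError(f"ML value-exponent {a} <= 1; rank exponent undefined")
        alpha = 1.0 / (a - 1.0)
        # delta method: sd(alpha) = sd(a)/(a-1)^2 with sd(a) = (a-1)/sqrt(m)
        stderr = 1.0 / ((a - 1.0) * np.sqrt(m))
        return PowerLawFit(
            alpha=float(alpha),
            method=CLAUSET,
            rank_range=(n_min, int(ranks[-1])),
            goodness=float(ks),
            stderr=float(stderr),
            n_used=int(m),
        )
    raise ValueError(f"unknown fit method: {method!r}")


def powerlaw_ml_exponent(
    samples: Sequence[float],
    xmin: Union[str, float] = "scan",
    max_xmin_candidates: int = 200,
    min_tail: int = 10,
) -> Tuple[float, float, float, int]:
    """Continuous-power-law ML exponent with KS goodness of fit.

    For samples x >= xmin drawn from p(x) ~ x^(-a), the ML estimate is

        a = 1 + m / sum(log(x_i / xmin)).

    With ``xmin="scan"`` the lower cutoff is chosen among (up to
    ``max_xmin_candidates`` log-spaced) observed values to minimize the
    Kolmogorov-Smirnov distance between the tail and the fitted law.

    Returns ``(a, xmin, ks, m)`` where m is the tail size used.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[x > 0]
    if len(x) < min_tail:
        raise FitError(f"need at least {min_tail} positive samples")

    def _fit_at(cutoff: float):
        tail = x[x >= cutoff]
        m = len(tail)
        if m < min_tail:
            return None
        log_ratio = np.sum(np.log(tail / cutoff))
        if log_ratio <= 0:
            return None
        a = 1.0 + m / log_ratio
        # KS distance between empirical tail CDF and F(v) = 1 - (v/xmin)^(1-a)
        cdf = 1.0 - (tail / cutoff) ** (1.0 - a)
        grid = np.arange(m)
        ks = float(np.max(np.maximum(cdf - grid / m, (grid + 1) / m - cdf)))
        return a, ks, m

    if xmin != "scan":
        cutoff = float(xmin)
        fit = _fit_at(cutoff)
        if fit is None:
            raise FitError("tail above xmin too small or degenerate")
        a, ks, m = fit
        return a, cutoff, ks, m

    candidates = np.unique(x[: len(x) - min_tail + 1])
    if len(candidates) > max_xmin_candidates:
        idx = np.unique(
            np.geomspace(1, len(candidates), max_xmin_candidates).astype(int) - 1
        )
        candidates = candidates[idx]
    best = None
    for cutoff in candidates:
        fit = _fit_at(cutoff)
        if fit is None:
            continue
        a, ks, m = fit
        if best is None or ks < best[2]:
            best = (a, float(cutoff), ks, m)
    if best is None:
        raise FitError("no admissible lower cutoff found")
    return best


def cvpca(repeat1: np.ndarray, repeat2: np.ndarray) -> CvPCAResult:
    """Cross-validated PCA signal variances from two repeats.

    Both repeats are centered with repeat 1's unit means; eigenvectors u_i
    come from repeat 1's covariance, and

        signal_variance[i] = (1/S) (u_i^T X1c) . (u_i^T X2c)

    Noise that is independent across repeats cancels in expectation, so
    these estimate the stimulus-related component variances.  Negative
    values are retained.  With repeat2 == repeat1 the result equals the
    plain PCA eigenspectrum.
    """
    x1 = np.asarray(repeat1, dtype=float)
    x2 = np.asarray(repeat2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 2:
        raise DimensionError("repeats must be two N x S matrices of equal shape")
    n_samples = x1.shape[1]
    if n_samples < 2:
        raise InsufficientSamplesError("need at least 2 samples per repeat")
    mu = x1.mean(axis=1, keepdims=True)
    x1c = x1 - mu
    x2c = x2 - mu
    cov1 = (x1c @ x1c.T) / n_samples
    eigenvalues, eigenvectors = np.linalg.eigh(cov1)
    order = np.argsort(eigenvalues)[::-1]
    u = eigenvectors[:, order]
    p1 = u.T @ x1c
    p2 = u.T @ x2c
    signal = (p1 * p2).sum(axis=1) / n_samples
    return CvPCAResult(signal_variances=signal, basis="repeat1")


def cplusd_threshold(d: Union[int, float]) -> float:
    """Critical exponent alpha_c = 1 + 2/d (d = inf gives 1)."""
    if d == np.inf:
        return 1.0
    d = float(d)
    if d < 1:
        raise DimensionError("input dimension d must be >= 1 (or inf)")
    return 1.0 + 2.0 / d


def classify_manifold(alpha: float, d: Union[int, float]) -> ManifoldClass:
    """Classify a representation manifold from its spectrum decay exponent.

    alpha < 1: neither continuous nor differentiable; 1 < alpha < 1 + 2/d:
    continuous but not differentiable; alpha > 1 + 2/d: continuous and
    differentiable (C+D).  Exact boundary values get the weaker class with
    ``boundary=True``.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    threshold = cplusd_threshold(d)
    if alpha < 1.0:
        label, boundary = NEITHER, False
    elif alpha == 1.0:
        label, boundary = NEITHER, True
    elif alpha < threshold:
        label, boundary = CONTINUOUS_NOT_DIFFERENTIABLE, False
    elif alpha == threshold:
        label, boundary = CONTINUOUS_NOT_DIFFERENTIABLE, True
    else:
        label, boundary = CPLUSD, False
    return ManifoldClass(label=label, boundary=boundary, alpha=float(alpha), threshold=threshold)
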