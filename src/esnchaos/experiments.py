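"""Reproducible experiment pipelines over synthetic image ensembles.

Three studies are orchestrated here:

* :func:`run_phase_diagram` — sweep the (spectral radius rho, input gain
  eps) plane, recording the eigenspectrum decay exponent alpha and the
  maximum Lyapunov exponent at each grid point.
* :func:`run_dimensionality_experiment` — spectra and exponents for
  inputs of controlled embedding dimension d (and naturalistic inputs for
  d = inf), in three conditions: noiseless PCA, noisy raw PCA, and noisy
  cvPCA; compared against the C+D threshold 1 + 2/d.
* :func:`run_classification_sweep` — classification error, MLE and alpha
  as functions of rho at fixed eps, locating the performance peak
  relative to the order-chaos transition.

Every run is exactly reproducible from its :class:`ExperimentConfig` and
master seed; per-grid-point seeds are derived from the master seed and the
point's own coordinates, so results do not depend on which other grid
points are present or on execution order.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .dynamics import estimate_mle
from .exceptions import CalibrationError
from .images import (
    ImageSet,
    generate_labeled_images,
    generate_lowrank_images,
    generate_naturalistic_images,
    load_image_set,
)
from .readout import encode_reservoir_model, evaluate, train_readout
from .reservoir import (
    ReservoirConfig,
    build_reservoir,
    iter_trajectories,
    run_ensemble,
)
from .spectrum import (
    EigenSpectrum,
    PowerLawFit,
    classify_manifold,
    compute_eigenspectrum,
    cplusd_threshold,
    cvpca,
    fit_powerlaw,
)

__all__ = [
    "ExperimentConfig",
    "make_images",
    "point_seed",
    "run_phase_diagram",
    "calibrate_edge",
    "run_dimensionality_experiment",
    "run_classification_sweep",
    "full_scale_profile",
]

_GENERATORS = ("naturalistic", "lowrank", "labeled", "file")


@dataclasses.dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run.

    The defaults are the desk-scale profile used throughout the test
    suite: reservoirs of N = 200 units driven by M = 200 naturalistic
    30 x 30 images (N = 100 for classification sweeps).  See
    :func:`full_scale_profile` for the full-scale settings.
    """

    image_generator: str = "naturalistic"
    image_params: Dict = dataclasses.field(
        default_factory=lambda: {"n_images": 200, "height": 30, "width": 30}
    )
    n_units: int = 200
    density: float = 0.10
    rho: float = 0.95
    eps: float = 0.6
    noise_amplitude: float = 0.4  # used only by the noisy conditions
    washout: int = 0
    state_reset_policy: str = "reset-per-image"
    rho_grid: List[float] = dataclasses.field(default_factory=list)
    eps_grid: List[float] = dataclasses.field(default_factory=list)
    fit_method: str = "loglog-regression"
    rank_range: Optional[Tuple[int, int]] = None
    ridge_penalty_model: float = 1.0
    ridge_penalty_readout: float = 1.0
    standardize: bool = True
    mle_gamma0: float = 1e-12
    mle_washout: int = 100
    mle_steps: int = 500
    mle_trials: int = 5
    seed: int = 0
    out_dir: Optional[str] = None
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.image_generator not in _GENERATORS:
            raise ValueError(
                f"image_generator must be one of {_GENERATORS}, "
                f"got {self.image_generator!r}"
            )
        if self.n_units < 1 or not (0 < self.density <= 1):
            raise ValueError("invalid reservoir size or density")

    def replace(self, **kwargs) -> "ExperimentConfig":
        return dataclasses.replace(self, **kwargs)

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ExperimentConfig":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if payload.get("rank_range") is not None:
            payload["rank_range"] = tuple(payload["rank_range"])
        return cls(**payload)


def full_scale_profile() -> ExperimentConfig:
    """Full-scale settings (N = 2000 reservoirs, M = 2800 images).

    Provided for completeness; the test suite runs only the desk-scale
    defaults.
    """
    return ExperimentConfig(
        image_params={"n_images": 2800, "height": 90, "width": 90},
        n_units=2000,
        mle_steps=1000,
        mle_trials=10,
    )


def make_images(config: ExperimentConfig, seed: Optional[int] = None) -> ImageSet:
    """Generate (or load) the image ensemble named by the config."""
    params = dict(config.image_params)
    gen = config.image_generator
    if gen == "file":
        return load_image_set(params["path"])
    params.setdefault("seed", config.seed if seed is None else seed)
    if gen == "naturalistic":
        return generate_naturalistic_images(**params)
    if gen == "lowrank":
        return generate_lowrank_images(**params)
    return generate_labeled_images(**params)


def point_seed(master_seed: int, *coords: float) -> int:
    """Per-grid-point seed derived from the point's own coordinates.

    Keying on the (rho, eps, ...) values rather than a grid index makes a
    point's result independent of which other grid points are present and
    of execution order (serial or parallel).
    """
    words = np.frombuffer(
        np.asarray(coords, dtype=np.float64).tobytes(), dtype=np.uint32
    )
    seq = np.random.SeedSequence([int(master_seed), *(int(w) for w in words)])
    return int(seq.generate_state(1)[0] % (2**31))


def _reservoir_config(config: ExperimentConfig, rho, eps, seed, noise=0.0):
    return ReservoirConfig(
        n_units=config.n_units,
        density=config.density,
        spectral_radius=rho,
        input_scaling=eps,
        noise_amplitude=noise,
        seed=seed,
        state_reset_policy=config.state_reset_policy,
        washout=config.washout,
    )


def _alpha_and_mle(config, images, rho, eps, seed):
    rc = _reservoir_config(config, rho, eps, seed)
    weights = build_reservoir(rc, n_inputs=images.height)
    activity = run_ensemble(weights, images, rc)
    spec = compute_eigenspectrum(activity)
    fit = fit_powerlaw(spec, method=config.fit_method, rank_range=config.rank_range)
    mle = estimate_mle(
        weights,
        rc,
        images,
        gamma0=config.mle_gamma0,
        washout=config.mle_washout,
        n_steps=config.mle_steps,
        n_trials=config.mle_trials,
        seed=seed,
    )
    return spec, fit, mle


def _phase_point(config, images, rho, eps) -> Dict:
    seed = point_seed(config.seed, rho, eps)
    record: Dict = {"rho": rho, "eps": eps, "seed": seed, "failed": False, "error": ""}
    try:
        _, fit, mle = _alpha_and_mle(config, images, rho, eps, seed)
        d = images.intrinsic_dim if images.intrinsic_dim is not None else math.inf
        manifold = classify_manifold(fit.alpha, d)
        record.update(
            mle=mle.mle,
            mle_stderr=mle.std_error,
            alpha=fit.alpha,
            fit_method=fit.method,
            fit_goodness=fit.goodness,
            fit_rank_min=fit.rank_range[0],
            fit_rank_max=fit.rank_range[1],
            manifold_class=manifold.label,
        )
    except Exception as exc:  # per-point failures recorded; run continues
        record.update(
            failed=True,
            error=f"{type(exc).__name__}: {exc}",
            mle=np.nan,
            mle_stderr=np.nan,
            alpha=np.nan,
            fit_method="",
            fit_goodness=np.nan,
            fit_rank_min=-1,
            fit_rank_max=-1,
            manifold_class="",
        )
    return record


def _write_outputs(config: ExperimentConfig, name: str, table: pd.DataFrame) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{name}.csv", index=False)
    meta = {
        "experiment": name,
        "config": json.loads(config.to_json()),
        "n_records": int(len(table)),
    }
    (out / f"{name}.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def run_phase_diagram(config: ExperimentConfig) -> pd.DataFrame:
    """Sweep the (rho, eps) grid: alpha, MLE and manifold class per point.

    Grid points are independent (per-point derived seeds) and may be
    executed in parallel with ``config.n_jobs``.
    """
    if not config.rho_grid or not config.eps_grid:
        raise ValueError("rho_grid and eps_grid must both be nonempty")
    images = make_images(config)
    points = [(r, e) for r in config.rho_grid for e in config.eps_grid]
    if config.n_jobs != 1:
        records = Parallel(n_jobs=config.n_jobs)(
            delayed(_phase_point)(config, images, r, e) for r, e in points
        )
    else:
        records = [_phase_point(config, images, r, e) for r, e in points]
    table = pd.DataFrame.from_records(records)
    _write_outputs(config, "phase_diagram", table)
    return table


def calibrate_edge(
    config: ExperimentConfig,
    target_mle_window: Tuple[float, float] = (-0.02, 0.0),
    search_variable: str = "rho",
    bracket: Tuple[float, float] = (0.2, 2.5),
    max_iter: int = 30,
    mle_fn: Optional[Callable[[float], float]] = None,
) -> Tuple[float, float, List[Tuple[float, float]]]:
    """Tune rho (or eps) until the MLE lands just below zero.

    Bisection on the (monotone along the searched axis, for the regimes of
    interest) map parameter -> MLE until the estimate falls inside
    ``target_mle_window`` (default [-0.02, 0)).  Returns
    ``(tuned value, achieved MLE, scanned curve)``.

    ``mle_fn`` may override the measurement (used with synthetic stubs in
    tests); by default the config's image ensemble drives the reservoir.
    """
    lo_w, hi_w = target_mle_window
    if hi_w > 0 or lo_w >= hi_w:
        raise ValueError("target window must satisfy lo < hi <= 0")
    if search_variable not in ("rho", "eps"):
        raise ValueError("search_variable must be 'rho' or 'eps'")

    if mle_fn is None:
        images = make_images(config)

        def mle_fn(value: float) -> float:
            rho = value if search_variable == "rho" else config.rho
            eps = value if search_variable == "eps" else config.eps
            seed = point_seed(config.seed, 0)
            rc = _reservoir_config(config, rho, eps, seed)
            weights = build_reservoir(rc, n_inputs=images.height)
            est = estimate_mle(
                weights,
                rc,
                images,
                gamma0=config.mle_gamma0,
                washout=config.mle_washout,
                n_steps=config.mle_steps,
                n_trials=config.mle_trials,
                seed=seed,
            )
            return est.mle

    # the MLE increases with rho and decreases with eps in the search regime
    sign = 1.0 if search_variable == "rho" else -1.0
    curve: List[Tuple[float, float]] = []

    def measure(value: float) -> float:
        m = mle_fn(value)
        curve.append((float(value), float(m)))
        return m

    a, b = float(bracket[0]), float(bracket[1])
    fa, fb = measure(a), measure(b)
    for value, f in ((a, fa), (b, fb)):
        if lo_w <= f < hi_w:
            return value, f, curve
    ga, gb = sign * fa, sign * fb
    if not (ga < 0.0 <= gb):
        raise CalibrationError(
            f"MLE window {target_mle_window} not bracketed by "
            f"{search_variable} in {bracket}: endpoints gave {fa:.4f}, {fb:.4f}",
            curve=curve,
        )
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        fm = measure(mid)
        if lo_w <= fm < hi_w:
            return mid, fm, curve
        if sign * fm >= 0.0:
            b = mid
        else:
            a = mid
    raise CalibrationError(
        f"calibration did not reach the window {target_mle_window} in "
        f"{max_iter} bisection steps",
        curve=curve,
    )


@dataclasses.dataclass
class DimensionalityResult:
    """Spectra and fits for one input dimensionality, in three conditions."""

    d: float  # embedding dimension (inf for naturalistic)
    threshold: float  # 1 + 2/d
    input_spectrum: EigenSpectrum  # pixel-ensemble eigenspectrum
    noiseless_spectrum: EigenSpectrum
    noiseless_fit: PowerLawFit
    noisy_raw_spectrum: EigenSpectrum
    noisy_raw_fit: PowerLawFit
    cvpca_signal_variances: np.ndarray
    cvpca_fit: PowerLawFit
    manifold_noiseless: str
    manifold_cvpca: str


def run_dimensionality_experiment(
    config: ExperimentConfig,
    d_list: Sequence[Union[int, float]] = (4, 8, math.inf),
) -> Dict[float, DimensionalityResult]:
    """Spectra vs input dimensionality at a fixed (calibrated) reservoir.

    For each d the ensemble is regenerated (low-rank for finite d,
    naturalistic for d = inf) with the config's n_images/height/width.
    Conditions per d: noiseless PCA; noisy raw PCA (xi =
    ``config.noise_amplitude``); cvPCA over two noisy repeats sharing the
    signal with independent noise streams.  The reservoir operating point
    (``config.rho``, ``config.eps``) is expected to be pre-calibrated to
    the edge of chaos via :func:`calibrate_edge`.
    """
    params = dict(config.image_params)
    n_images = params.get("n_images", 200)
    height = params.get("height", 30)
    width = params.get("width", 30)
    results: Dict[float, DimensionalityResult] = {}
    for d in d_list:
        seed = point_seed(config.seed, 2.0, float(d))
        if math.isinf(d):
            images = generate_naturalistic_images(
                n_images, height, width, seed=seed
            )
        else:
            images = generate_lowrank_images(
                n_images, height, width, d=int(d), seed=seed
            )
        # pixel-ensemble spectrum: pixels are variables, images are samples
        input_spectrum = compute_eigenspectrum(images.flattened().T)

        rc = _reservoir_config(config, config.rho, config.eps, seed)
        weights = build_reservoir(rc, n_inputs=images.height)
        clean = run_ensemble(weights, images, rc)
        clean_spec = compute_eigenspectrum(clean)
        clean_fit = fit_powerlaw(
            clean_spec, method=config.fit_method, rank_range=config.rank_range
        )

        rc_noisy = rc.replace(noise_amplitude=config.noise_amplitude)
        repeat1 = run_ensemble(
            weights, images, rc_noisy, rng=np.random.default_rng(seed + 1)
        )
        repeat2 = run_ensemble(
            weights, images, rc_noisy, rng=np.random.default_rng(seed + 2)
        )
        raw_spec = compute_eigenspectrum(repeat1)
        raw_fit = fit_powerlaw(
            raw_spec, method=config.fit_method, rank_range=config.rank_range
        )
        cv = cvpca(repeat1, repeat2)
        cv_fit = fit_powerlaw(
            cv, method=config.fit_method, rank_range=config.rank_range
        )
        threshold = cplusd_threshold(d)
        results[float(d)] = DimensionalityResult(
            d=float(d),
            threshold=threshold,
            input_spectrum=input_spectrum,
            noiseless_spectrum=clean_spec,
            noiseless_fit=clean_fit,
            noisy_raw_spectrum=raw_spec,
            noisy_raw_fit=raw_fit,
            cvpca_signal_variances=cv.signal_variances,
            cvpca_fit=cv_fit,
            manifold_noiseless=classify_manifold(clean_fit.alpha, d).label,
            manifold_cvpca=classify_manifold(cv_fit.alpha, d).label,
        )
    if config.out_dir is not None:
        rows = []
        for d, res in results.items():
            rows.append(
                {
                    "d": d,
                    "threshold": res.threshold,
                    "alpha_noiseless": res.noiseless_fit.alpha,
                    "alpha_noisy_raw": res.noisy_raw_fit.alpha,
                    "alpha_cvpca": res.cvpca_fit.alpha,
                    "manifold_noiseless": res.manifold_noiseless,
                    "manifold_cvpca": res.manifold_cvpca,
                }
            )
        _write_outputs(config, "dimensionality", pd.DataFrame(rows))
    return results


def _encode_images(weights, images: ImageSet, rc: ReservoirConfig, penalty: float):
    return np.asarray(
        [
            encode_reservoir_model(traj, penalty).theta
            for traj in iter_trajectories(weights, images, rc)
        ]
    )


def run_classification_sweep(
    config: ExperimentConfig,
    rho_list: Sequence[float],
    eps: float,
    n_train_per_class: int = 50,
    n_test_per_class: int = 25,
) -> pd.DataFrame:
    """Classification error, MLE and alpha vs rho at fixed eps.

    The labeled ensemble (``config.image_params``: n_classes, height,
    width, noise_sd) is generated once, split per class into train/test,
    and re-encoded for every rho.  alpha and the MLE are measured on the
    training activity/drive.
    """
    params = dict(config.image_params)
    n_classes = params.get("n_classes", 4)
    height = params.get("height", 30)
    width = params.get("width", 30)
    noise_sd = params.get("noise_sd", 0.05)
    total = n_train_per_class + n_test_per_class
    images = generate_labeled_images(
        total, n_classes, height, width, noise_sd=noise_sd, seed=config.seed
    )
    train_idx, test_idx = [], []
    for c in range(n_classes):
        offset = c * total
        train_idx.extend(range(offset, offset + n_train_per_class))
        test_idx.extend(range(offset + n_train_per_class, offset + total))
    train_set = images.subset(train_idx)
    test_set = images.subset(test_idx)

    records = []
    for rho in rho_list:
        seed = point_seed(config.seed, 3.0, float(rho), float(eps))
        record: Dict = {
            "rho": float(rho),
            "eps": float(eps),
            "seed": seed,
            "failed": False,
            "error": "",
        }
        try:
            rc = _reservoir_config(config, rho, eps, seed)
            weights = build_reservoir(rc, n_inputs=height)
            theta_train = _encode_images(
                weights, train_set, rc, config.ridge_penalty_model
            )
            theta_test = _encode_images(
                weights, test_set, rc, config.ridge_penalty_model
            )
            model = train_readout(
                theta_train,
                train_set.labels,
                ridge_penalty=config.ridge_penalty_readout,
                standardize=config.standardize,
            )
            report = evaluate(model, theta_test, test_set.labels)
            activity = run_ensemble(weights, train_set, rc)
            fit = fit_powerlaw(
                compute_eigenspectrum(activity),
                method=config.fit_method,
                rank_range=config.rank_range,
            )
            mle = estimate_mle(
                weights,
                rc,
                train_set,
                gamma0=config.mle_gamma0,
                washout=config.mle_washout,
                n_steps=config.mle_steps,
                n_trials=config.mle_trials,
                seed=seed,
            )
            record.update(
                error_rate=report.error_rate,
                mle=mle.mle,
                mle_stderr=mle.std_error,
                alpha=fit.alpha,
            )
        except Exception as exc:
            record.update(
                failed=True,
                error=f"{type(exc).__name__}: {exc}",
                error_rate=np.nan,
                mle=np.nan,
                mle_stderr=np.nan,
                alpha=np.nan,
            )
        records.append(record)
    table = pd.DataFrame.from_records(records)
    _write_outputs(config, "classification_sweep", table)
    return table
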