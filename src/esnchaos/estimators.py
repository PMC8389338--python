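"""Scikit-learn-style estimators over the reservoir / readout core.

``ReservoirModelSpace`` is a transformer turning a stack of grayscale
images (M, H, W) into reservoir-model-space feature vectors (M, N(N+1));
``RidgeReadout`` is the one-hot ridge classifier over those features;
``ESNClassifier`` chains the two.  All three follow the sklearn estimator
protocol (get_params/set_params, fitted attributes with trailing
underscores) and compose with sklearn pipelines and model selection.
"""

from __future__ import annotations



import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import DimensionError
from .readout import decision_scores, encode_reservoir_model, evaluate, train_readout
from .reservoir import (
    RESET_PER_IMAGE,
    ReservoirConfig,
    build_reservoir,
    run_sequence,
)
from .images import ImageSet, image_to_sequence

__all__ = ["ReservoirModelSpace", "RidgeReadout", "ESNClassifier"]


def _as_image_stack(X) -> np.ndarray:
    if isinstance(X, ImageSet):
        return X.images
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 3:
        raise DimensionError(
            f"expected images with shape (M, H, W) or an ImageSet, got {arr.shape}"
        )
    return arr


class ReservoirModelSpace(TransformerMixin, BaseEstimator):
    """Transform images into reservoir-model-space vectors theta.

    ``fit`` samples the fixed random reservoir (weights are never
    trained); ``transform`` drives it with each image, read column by
    column, and ridge-fits the linear one-step model of the resulting
    trajectory, returning theta = [vec(W_x); w_x] per image.

    Parameters
    ----------
    n_units : int
        Reservoir size N (feature dimension is N(N+1)).
    spectral_radius, input_scaling, density, noise_amplitude, washout :
        Reservoir hyperparameters, see :class:`ReservoirConfig`.
    ridge_penalty : float
        Penalty of the per-image one-step model fit.
    random_state : int
        Seed for reservoir sampling (and the noise stream, if any).
    """

    def __init__(
        self,
        n_units: int = 100,
        spectral_radius: float = 0.9,
        input_scaling: float = 0.6,
        density: float = 0.10,
        noise_amplitude: float = 0.0,
        washout: int = 0,
        state_reset_policy: str = RESET_PER_IMAGE,
        ridge_penalty: float = 1.0,
        random_state: int = 0,
    ):
        self.n_units = n_units
        self.spectral_radius = spectral_radius
        self.input_scaling = input_scaling
        self.density = density
        self.noise_amplitude = noise_amplitude
        self.washout = washout
        self.state_reset_policy = state_reset_policy
        self.ridge_penalty = ridge_penalty
        self.random_state = random_state

    def _config(self) -> ReservoirConfig:
        return ReservoirConfig(
            n_units=self.n_units,
            spectral_radius=self.spectral_radius,
            input_scaling=self.input_scaling,
            density=self.density,
            noise_amplitude=self.noise_amplitude,
            seed=self.random_state,
            state_reset_policy=self.state_reset_policy,
            washout=self.washout,
        )

    def fit(self, X, y=None):
        images = _as_image_stack(X)
        self.config_ = self._config()
        self.weights_ = build_reservoir(self.config_, n_inputs=images.shape[1])
        self.n_features_in_ = images.shape[1] * images.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        images = _as_image_stack(X)
        rng = (
            np.random.default_rng(self.random_state)
            if self.noise_amplitude > 0
            else None
        )
        thetas = []
        for idx in range(images.shape[0]):
            seq = image_to_sequence(images[idx], source_image_index=idx)
            traj = run_sequence(self.weights_, seq, self.config_, rng=rng)
            thetas.append(encode_reservoir_model(traj, self.ridge_penalty).theta)
        return np.asarray(thetas)


class RidgeReadout(ClassifierMixin, BaseEstimator):
    """One-hot ridge classifier with unpenalized bias.

    Features are z-scored over the training set by default (parameters
    frozen for prediction); prediction is the argmax of the linear readout
    with ties broken toward the lowest class index.
    """

    def __init__(self, alpha: float = 1.0, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.model_ = train_readout(
            X, y, ridge_penalty=self.alpha, standardize=self.standardize
        )
        self.classes_ = self.model_.classes
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        return decision_scores(self.model_, np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def error_rate(self, X, y) -> float:
        """1 - accuracy, with the package's confusion-count bookkeeping."""
        check_is_fitted(self, "model_")
        report = evaluate(self.model_, np.asarray(X, dtype=float), y)
        return report.error_rate


class ESNClassifier(ClassifierMixin, BaseEstimator):
    """Image classifier: reservoir-model-space encoding + ridge readout.

    Equivalent to ``Pipeline([ReservoirModelSpace(...), RidgeReadout(...)])``
    with a flat parameter surface.
    """

    def __init__(
        self,
        n_units: int = 100,
        spectral_radius: float = 0.9,
        input_scaling: float = 0.6,
        density: float = 0.10,
        noise_amplitude: float = 0.0,
        washout: int = 0,
        ridge_penalty_model: float = 1.0,
        ridge_penalty_readout: float = 1.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.n_units = n_units
        self.spectral_radius = spectral_radius
        self.input_scaling = input_scaling
        self.density = density
        self.noise_amplitude = noise_amplitude
        self.washout = washout
        self.ridge_penalty_model = ridge_penalty_model
        self.ridge_penalty_readout = ridge_penalty_readout
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        self.encoder_ = ReservoirModelSpace(
            n_units=self.n_units,
            spectral_radius=self.spectral_radius,
            input_scaling=self.input_scaling,
            density=self.density,
            noise_amplitude=self.noise_amplitude,
            washout=self.washout,
            ridge_penalty=self.ridge_penalty_model,
            random_state=self.random_state,
        ).fit(X)
        theta = self.encoder_.transform(X)
        self.readout_ = RidgeReadout(
            alpha=self.ridge_penalty_readout, standardize=self.standardize
        ).fit(theta, y)
        self.classes_ = self.readout_.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "readout_")
        return self.readout_.decision_function(self.encoder_.transform(X))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def error_rate(self, X, y) -> float:
        check_is_fitted(self, "readout_")
        return self.readout_.error_rate(self.encoder_.transform(X), y)
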