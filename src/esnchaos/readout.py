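"""Reservoir-model-space encoding and ridge readout classification.

Each image's reservoir trajectory is summarized by the parameters of the
best linear one-step predictor of the dynamics,

    x(t+1) = W_x x(t) + w_x,

fitted by ridge regression over the image's T-1 state transitions.  The
vector theta = [vec(W_x); w_x] of length N(N+1) characterizes the
reservoir's dynamical state during that image and is the classification
feature ("reservoir model space").  A linear readout

    y = W_out theta + w_out

is then ridge-trained against one-hot class targets; the predicted class
is the argmax of y.

Both ridge problems leave the bias unpenalized (solved exactly via
centering) and are deterministic.  The closed-form solves here are
independently cross-checked against scikit-learn's Ridge in the test
suite.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .exceptions import DimensionError, InsufficientSamplesError, InvalidClassCountError
from .reservoir import StateTrajectory

__all__ = [
    "ModelSpaceEncoding",
    "ReadoutModel",
    "ClassificationReport",
    "encode_reservoir_model",
    "one_hot",
    "train_readout",
    "decision_scores",
    "evaluate",
    "ridge_fit",
]


@dataclasses.dataclass
class ModelSpaceEncoding:
    """theta = [vec(W_x); w_x], length N(N+1), for one image."""

    theta: np.ndarray
    ridge_penalty: float
    source_image_index: Optional[int] = None

    def __len__(self) -> int:
        return len(self.theta)


@dataclasses.dataclass
class ReadoutModel:
    """Trained linear readout over the model space."""

    W_out: np.ndarray  # (F, P)
    w_out: np.ndarray  # (F,)
    ridge_penalty: float
    classes: np.ndarray  # class ids in prediction order
    feature_mean: Optional[np.ndarray] = None  # standardization parameters
    feature_scale: Optional[np.ndarray] = None

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclasses.dataclass
class ClassificationReport:
    """Error rate and confusion counts over an evaluation set."""

    error_rate: float
    confusion: np.ndarray  # (F, F), rows = true class, cols = predicted
    n_evaluated: int


def ridge_fit(
    x: np.ndarray, y: np.ndarray, penalty: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Multi-output ridge with unpenalized intercept.

    Minimizes sum_i ||y_i - W x_i - b||^2 + penalty * ||W||_F^2 for
    ``x`` (n_samples, n_features) and ``y`` (n_samples, n_outputs).
    Solved in closed form on centered data; the dual (n_samples-sized)
    system is used when n_features > n_samples.  Returns ``(W, b)`` with
    W of shape (n_outputs, n_features).
    """
    if penalty <= 0:
        raise ValueError("ridge penalty must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise DimensionError("x (n, p) and y (n, f) must share n_samples")
    n_samples, n_features = x.shape
    x_mean = x.mean(axis=0)
    y_mean = y.mean(axis=0)
    xc = x - x_mean
    yc = y - y_mean
    if n_features <= n_samples:
        gram = xc.T @ xc + penalty * np.eye(n_features)
        coef = np.linalg.solve(gram, xc.T @ yc)  # (p, f)
    else:  # dual form: coef = X^T (X X^T + penalty I)^-1 Y
        gram = xc @ xc.T + penalty * np.eye(n_samples)
        coef = xc.T @ np.linalg.solve(gram, yc)
    w = coef.T  # (f, p)
    b = y_mean - w @ x_mean
    return w, b


def encode_reservoir_model(
    trajectory: Union[StateTrajectory, np.ndarray],
    ridge_penalty: float = 1.0,
) -> ModelSpaceEncoding:
    """Encode a trajectory as theta = [vec(W_x); w_x].

    (W_x, w_x) minimize sum_t ||x(t+1) - W_x x(t) - w_x||^2 +
    ridge_penalty * ||W_x||_F^2 over the trajectory's T-1 transitions
    (bias unpenalized).  vec() is row-major.
    """
    if ridge_penalty <= 0:
        raise ValueError("ridge_penalty must be > 0 (guarantees uniqueness)")
    states = trajectory.states if isinstance(trajectory, StateTrajectory) else None
    source = trajectory.source_image_index if states is not None else None
    if states is None:
        states = np.asarray(trajectory, dtype=float)
    if states.ndim != 2:
        raise DimensionError("trajectory states must be an N x T matrix")
    n_units, t_steps = states.shape
    if t_steps < 3:
        raise InsufficientSamplesError(
            f"need T >= 3 (at least 2 transitions), got T = {t_steps}"
        )
    x_past = states[:, :-1].T  # (T-1, N)
    x_next = states[:, 1:].T
    w_x, b_x = ridge_fit(x_past, x_next, ridge_penalty)
    theta = np.concatenate([w_x.ravel(), b_x])
    return ModelSpaceEncoding(
        theta=theta, ridge_penalty=ridge_penalty, source_image_index=source
    )


def one_hot(labels: Sequence[int], n_classes: int) -> np.ndarray:
    """Exact one-hot targets for integer labels in [0, n_classes)."""
    labels = np.asarray(labels, dtype=int)
    if n_classes < 2:
        raise InvalidClassCountError("n_classes must be >= 2")
    if labels.min(initial=0) < 0 or (labels >= n_classes).any():
        raise ValueError("labels must lie in [0, n_classes)")
    return np.eye(n_classes)[labels]


def _encoding_matrix(encodings) -> np.ndarray:
    if isinstance(encodings, np.ndarray) and encodings.ndim == 2:
        return np.asarray(encodings, dtype=float)
    rows = [e.theta if isinstance(e, ModelSpaceEncoding) else np.asarray(e) for e in encodings]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise DimensionError("all encodings must have the same length")
    return np.asarray(rows, dtype=float)


def train_readout(
    encodings: Union[Sequence[ModelSpaceEncoding], np.ndarray],
    labels: Sequence[int],
    ridge_penalty: float = 1.0,
    standardize: bool = True,
) -> ReadoutModel:
    """Ridge-train the linear readout theta -> one-hot targets.

    With ``standardize`` (default) features are z-scored per dimension
    over the training set (parameters frozen into the model for test
    time); zero-variance dimensions keep unit scale.  The bias is
    unpenalized.
    """
    theta = _encoding_matrix(encodings)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != theta.shape[0]:
        raise DimensionError("one label per encoding required")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise InvalidClassCountError(
            "training requires at least two distinct classes"
        )
    class_index = np.searchsorted(classes, labels)
    targets = one_hot(class_index, len(classes))
    feature_mean = feature_scale = None
    if standardize:
        feature_mean = theta.mean(axis=0)
        feature_scale = theta.std(axis=0)
        feature_scale = np.where(feature_scale > 0, feature_scale, 1.0)
        theta = (theta - feature_mean) / feature_scale
    w_out, b_out = ridge_fit(theta, targets, ridge_penalty)
    return ReadoutModel(
        W_out=w_out,
        w_out=b_out,
        ridge_penalty=ridge_penalty,
        classes=classes,
        feature_mean=feature_mean,
        feature_scale=feature_scale,
    )


def decision_scores(model: ReadoutModel, encodings) -> np.ndarray:
    """Raw readout outputs y = W_out theta + w_out, one row per encoding."""
    theta = _encoding_matrix(encodings)
    if theta.shape[1] != model.W_out.shape[1]:
        raise DimensionError(
            f"encoding length {theta.shape[1]} does not match model "
            f"({model.W_out.shape[1]})"
        )
    if model.feature_mean is not None:
        theta = (theta - model.feature_mean) / model.feature_scale
    return theta @ model.W_out.T + model.w_out


def evaluate(
    model: ReadoutModel,
    encodings: Union[Sequence[ModelSpaceEncoding], np.ndarray],
    labels: Sequence[int],
) -> ClassificationReport:
    """Classify encodings and tally the confusion matrix.

    Predicted class = argmax of the readout output (ties broken toward the
    lowest class index).
    """
    labels = np.asarray(labels, dtype=int)
    scores = decision_scores(model, encodings)
    predictions = model.classes[np.argmax(scores, axis=1)]
    n_classes = model.n_classes
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    true_index = np.searchsorted(model.classes, labels)
    pred_index = np.searchsorted(model.classes, predictions)
    np.add.at(confusion, (true_index, pred_index), 1)
    n_eval = len(labels)
    error_rate = 1.0 - np.trace(confusion) / n_eval
    return ClassificationReport(
        error_rate=float(error_rate), confusion=confusion, n_evaluated=n_eval
    )
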