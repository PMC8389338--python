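"""Echo state network reservoirs: construction and driven simulation.

The reservoir is a sparse random network of N tanh units driven by an
image-derived input sequence:

    x(t) = tanh( eps * W_in u(t) + W_res x(t-1) + xi * eta(t) )

with W_res an N x N sparse matrix (entries uniform [-1, 1], rescaled to a
target spectral radius rho), W_in an N x L1 dense matrix (uniform [-1, 1],
scaled at runtime by the input gain eps), and eta optional i.i.d. standard
normal noise of amplitude xi inside the activation argument.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional, Union

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as splinalg

from .exceptions import DegenerateMatrixError, DimensionError, InsufficientSamplesError
from .images import ImageSet, InputSequence, image_to_sequence

__all__ = [
    "ReservoirConfig",
    "ReservoirWeights",
    "StateTrajectory",
    "build_reservoir",
    "step",
    "run_sequence",
    "run_ensemble",
    "iter_trajectories",
    "spectral_radius",
]

# tanh(a) rounds to exactly +-1.0 in float64 for |a| >~ 19; states are kept
# strictly inside (-1, 1) by clipping to the nearest representable neighbour.
_BOUND = np.nextafter(1.0, 0.0)

RESET_PER_IMAGE = "reset-per-image"
CARRY_OVER = "carry-over"


@dataclasses.dataclass
class ReservoirConfig:
    """Hyperparameters of one echo state network instance.

    Attributes
    ----------
    n_units : int
        Number of reservoir units N.
    density : float
        Fraction of nonzero entries of W_res (default 0.10).
    spectral_radius : float
        Target largest eigenvalue magnitude rho of W_res (>= 0).
    input_scaling : float
        Input gain eps (>= 0).
    noise_amplitude : float
        White-noise amplitude xi inside the tanh argument (default 0).
    seed : int
        Seed for weight generation.
    state_reset_policy : str
        "reset-per-image" (default) or "carry-over" between images.
    washout : int
        Initial states discarded per sequence (default 0).
    """

    n_units: int
    spectral_radius: float
    input_scaling: float
    density: float = 0.10
    noise_amplitude: float = 0.0
    seed: int = 0
    state_reset_policy: str = RESET_PER_IMAGE
    washout: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.spectral_radius < 0:
            raise ValueError("spectral_radius must be >= 0")
        if self.input_scaling < 0:
            raise ValueError("input_scaling must be >= 0")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.state_reset_policy not in (RESET_PER_IMAGE, CARRY_OVER):
            raise ValueError(
                f"state_reset_policy must be '{RESET_PER_IMAGE}' or '{CARRY_OVER}'"
            )
        if self.washout < 0:
            raise ValueError("washout must be >= 0")

    def replace(self, **kwargs) -> "ReservoirConfig":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass
class ReservoirWeights:
    """Sampled reservoir coupling and input matrices."""

    W_res: sparse.csr_matrix  # N x N, rescaled to the target spectral radius
    W_in: np.ndarray  # N x L1 dense, unscaled (gain applied at runtime)
    achieved_spectral_radius: float
    seed: int

    @property
    def n_units(self) -> int:
        return self.W_res.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]


@dataclasses.dataclass
class StateTrajectory:
    """Unit activations for one input sequence (washout already removed)."""

    states: np.ndarray  # N x T
    source_image_index: Optional[int]
    config: ReservoirConfig

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1]


def spectral_radius(matrix, tol: float = 1e-10) -> float:
    """Largest eigenvalue magnitude of a (sparse) square matrix."""
    n = matrix.shape[0]
    if n <= 300:
        dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
        return float(np.max(np.abs(np.linalg.eigvals(dense))))
    try:
        # k > 1: with k=1 ARPACK can converge to one member of a clustered
        # set / complex pair that is not the true largest in magnitude.
        # A fixed start vector keeps the result independent of global RNG
        # state (and hence deterministic).
        v0 = np.random.default_rng(0).standard_normal(n)
        vals = splinalg.eigs(
            matrix,
            k=6,
            which="LM",
            return_eigenvectors=False,
            tol=tol,
            maxiter=10000,
            v0=v0,
        )
        return float(np.max(np.abs(vals)))
    except (splinalg.ArpackNoConvergence, RuntimeError):  # pragma: no cover
        dense = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
        return float(np.max(np.abs(np.linalg.eigvals(dense))))


def build_reservoir(config: ReservoirConfig, n_inputs: int) -> ReservoirWeights:
    """Sample W_res and W_in and impose the target spectral radius.

    W_res entries are Bernoulli(density)-masked uniform [-1, 1] draws,
    rescaled post hoc by rho / (current largest eigenvalue magnitude);
    W_in is dense uniform [-1, 1] with no rescaling (the gain eps is
    applied at simulation time).  Deterministic given ``config.seed``.
    """
    if n_inputs < 1:
        raise DimensionError("n_inputs must be >= 1")
    n = config.n_units
    rng = np.random.default_rng(config.seed)
    mask = rng.random((n, n)) < config.density
    rows, cols = np.nonzero(mask)
    values = rng.uniform(-1.0, 1.0, size=rows.size)
    w_res = sparse.csr_matrix((values, (rows, cols)), shape=(n, n))
    w_in = rng.uniform(-1.0, 1.0, size=(n, n_inputs))
    rho = config.spectral_radius
    if rho == 0.0:
        w_res = w_res * 0.0
        achieved = 0.0
    else:
        if rows.size == 0:
            raise DegenerateMatrixError(
                "sampled reservoir matrix is identically zero; cannot impose a "
                "positive spectral radius — retry with a different seed or a "
                "larger n_units * density"
            )
        current = spectral_radius(w_res)
        if current == 0.0:  # pragma: no cover - nilpotent sample
            raise DegenerateMatrixError(
                "sampled reservoir matrix has zero spectral radius; retry with "
                "a different seed"
            )
        w_res = w_res * (rho / current)
        achieved = rho
    return ReservoirWeights(
        W_res=w_res, W_in=w_in, achieved_spectral_radius=achieved, seed=config.seed
    )


def step(
    weights: ReservoirWeights,
    state: np.ndarray,
    input_vector: np.ndarray,
    config: ReservoirConfig,
    noise_draw: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One update x -> tanh(eps*W_in u + W_res x + xi*eta)."""
    state = np.asarray(state, dtype=float)
    input_vector = np.asarray(input_vector, dtype=float)
    if state.shape != (weights.n_units,):
        raise DimensionError(
            f"state must have shape ({weights.n_units},), got {state.shape}"
        )
    if input_vector.shape != (weights.n_inputs,):
        raise DimensionError(
            f"input must have shape ({weights.n_inputs},), got {input_vector.shape}"
        )
    pre = config.input_scaling * (weights.W_in @ input_vector) + weights.W_res @ state
    if config.noise_amplitude > 0.0 and noise_draw is not None:
        if noise_draw.shape != (weights.n_units,):
            raise DimensionError("noise_draw must have shape (n_units,)")
        pre = pre + config.noise_amplitude * noise_draw
    return np.clip(np.tanh(pre), -_BOUND, _BOUND)


def _as_steps(sequence) -> np.ndarray:
    if isinstance(sequence, InputSequence):
        return sequence.steps
    arr = np.asarray(sequence, dtype=float)
    if arr.ndim != 2:
        raise DimensionError("sequence must be an InputSequence or (T, L1) array")
    return arr


def run_sequence(
    weights: ReservoirWeights,
    sequence: Union[InputSequence, np.ndarray],
    config: ReservoirConfig,
    initial_state: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    source_image_index: Optional[int] = None,
) -> StateTrajectory:
    """Drive the reservoir through a full input sequence.

    The first ``config.washout`` states are discarded.  When
    ``noise_amplitude > 0`` an explicit ``rng`` stream must be supplied:
    two runs with different streams then share the signal but differ in
    noise, which is what cross-validated PCA requires.
    """
    steps_matrix = _as_steps(sequence)
    t_total = steps_matrix.shape[0]
    if t_total == 0:
        raise InsufficientSamplesError("empty input sequence")
    if steps_matrix.shape[1] != weights.n_inputs:
        raise DimensionError(
            f"sequence features ({steps_matrix.shape[1]}) != reservoir inputs "
            f"({weights.n_inputs})"
        )
    if config.washout >= t_total:
        raise InsufficientSamplesError(
            f"washout ({config.washout}) must be shorter than the sequence ({t_total})"
        )
    noisy = config.noise_amplitude > 0.0
    if noisy and rng is None:
        raise ValueError(
            "noise_amplitude > 0 requires an explicit rng stream (run_sequence "
            "repeats must control their noise streams independently)"
        )
    n = weights.n_units
    x = (
        np.zeros(n)
        if initial_state is None
        else np.asarray(initial_state, dtype=float).copy()
    )
    if x.shape != (n,):
        raise DimensionError(f"initial_state must have shape ({n},)")
    # input projections for all steps at once; recurrence stays sequential
    proj = config.input_scaling * (steps_matrix @ weights.W_in.T)  # (T, N)
    noise = (
        config.noise_amplitude * rng.standard_normal((t_total, n)) if noisy else None
    )
    w_res = weights.W_res
    states = np.empty((n, t_total))
    for t in range(t_total):
        pre = proj[t] + w_res @ x
        if noisy:
            pre = pre + noise[t]
        x = np.clip(np.tanh(pre), -_BOUND, _BOUND)
        states[:, t] = x
    return StateTrajectory(
        states=states[:, config.washout :],
        source_image_index=source_image_index,
        config=config,
    )


def iter_trajectories(
    weights: ReservoirWeights,
    image_set: ImageSet,
    config: ReservoirConfig,
    rng: Optional[np.random.Generator] = None,
) -> Iterator[StateTrajectory]:
    """Yield one trajectory per image, honouring the state-reset policy.

    Under "carry-over" the final state of image i seeds image i+1; under
    "reset-per-image" (default) every image starts from the zero state.
    A single noise stream spans all images.
    """
    state = np.zeros(weights.n_units)
    for idx in range(image_set.n_images):
        seq = image_to_sequence(image_set.images[idx], source_image_index=idx)
        initial = state if config.state_reset_policy == CARRY_OVER else None
        traj = run_sequence(
            weights, seq, config, initial_state=initial, rng=rng, source_image_index=idx
        )
        if config.state_reset_policy == CARRY_OVER:
            state = traj.states[:, -1].copy()
        yield traj


def run_ensemble(
    weights: ReservoirWeights,
    image_set: ImageSet,
    config: ReservoirConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Concatenated activity matrix N x (T' * M), image-major, time-minor."""
    blocks = [t.states for t in iter_trajectories(weights, image_set, config, rng=rng)]
    return np.concatenate(blocks, axis=1)
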