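# Methods

## Model

The package simulates echo state networks (ESNs): `N` tanh units coupled
by a fixed sparse random matrix `W_res` (10% nonzero entries, drawn
uniform on [-1, 1], rescaled post hoc so the largest eigenvalue magnitude
equals the target spectral radius `rho`), driven by an input layer
`W_in` (dense, uniform [-1, 1]) with gain `eps`:

    x(t) = tanh( eps * W_in u(t) + W_res x(t-1) + xi * eta(t) )

Grayscale images with pixel values in [0, 1] are read as multivariate
time series: column `t` of an H x W image is the length-H input vector
at step `t` (left-to-right scan, row 0 at the top).  The optional white
noise `eta` (i.i.d. standard normal per unit per step, amplitude `xi`)
enters inside the tanh argument.  Internal weights are never trained.

Two dynamical control parameters matter: `rho` destabilizes the
autonomous dynamics (echo state property typically lost above 1), while
`eps` stabilizes it by pushing units into the saturated tails of the
nonlinearity.  The operating regime is quantified by the maximum
Lyapunov exponent (MLE) `lambda`, the mean per-step log growth rate of
an infinitesimal state perturbation under the actual drive; `lambda > 0`
marks chaos and `lambda ~ 0-` the "edge of chaos".

## Maximum Lyapunov exponent

`estimate_mle` uses the clone-and-renormalize algorithm: after a
deterministic washout (default 100 steps), a clone of the trajectory is
displaced by `gamma0` (default 1e-12) on one randomly chosen unit; both
trajectories advance under identical input, the Euclidean separation
`gamma` is logged as `log(gamma/gamma0)` each step, and the clone is
pulled back onto the separation direction at distance `gamma0`.  The MLE
is the mean log ratio over `n_steps` (default 1000), averaged over
`n_trials` (default 10) independent perturbations, with the standard
error across trials reported.  Noise is forced off during estimation so
perturbation growth is deterministic, and the drive recycles the image
ensemble in order when more steps are needed than the ensemble provides.
The renormalized estimator is validated in the tests against a naive
unrenormalized two-trajectory log-slope oracle on instances where that
oracle is itself valid (clearly contracting dynamics, fit window after
modal alignment and above the float64 floor).

Two numerical details:

* In deeply saturated regimes (large `eps`) the one-step contraction can
  fall below float64 resolution and the separation collapses to exactly
  zero.  Such steps are unmeasurable; the perturbation is re-injected on
  a fresh random unit and the step is skipped (bounded number of
  re-injections).  Dropping the most contracting steps can only bias the
  estimate upward, which is conservative when the conclusion is
  "contracting".
* `np.tanh` rounds to exactly +-1.0 for arguments beyond ~19, so states
  are clipped to the nearest representable value inside (-1, 1) — a pure
  float64 guard that keeps trajectories strictly inside the open
  interval.

**The near-zero plateau.**  With zero input the origin is a fixed point
whose Jacobian is `W_res`, so `lambda = ln(rho)` exactly and the
order-chaos transition sits at `rho = 1`.  With any *finite* drive,
however weak, the instability for `rho` slightly above 1 pushes the
trajectory onto a weakly stable off-origin attractor where the measured
MLE hovers just below zero; across `N` from 200 to 2000 and `eps` from
1e-4 to 1e-1 we observe `lambda ~ -0.003..0` over `rho ~ 1.0-1.3`, with
the actual sign crossing drifting seed-dependently up to `rho ~ 1.4`.
The sweep tests that pin the crossing to `rho = 1` therefore use the
weak-drive limit (zero input, trajectory at the origin), which is the
regime where the analytic statement holds; the plateau itself is a real
feature of the driven system, not an estimator artifact.

## Eigenspectra and power-law exponents

PCA is computed over the full activity matrix `X in R^{N x (T*M)}`
(units are variables; time-stimulus samples are observations).  Rows are
mean-centered and the covariance is normalized by the sample count `S`
(population convention), which makes cross-validated PCA with identical
repeats reduce to plain PCA *exactly*.  Negative numerical dust below
`1e-12` of the total variance is clipped to zero.

The rank-ordered spectrum is modeled as `variance_n ~ n^(-alpha)` and
fitted two ways:

* **log-log regression** (default): least-squares slope of log variance
  vs log rank over ranks [11, min(500, n)] — the conventional fit range
  for neural eigenspectra; configurable and always reported.
* **Clauset-style ML + KS**: the continuous-power-law maximum-likelihood
  estimator with a KS-minimizing lower cutoff, applied to the eigenvalue
  *values*.  For an exact rank law `v_n ~ n^(-alpha)` the value
  distribution has CCDF `~ v^(-1/alpha)`, so the ML value-exponent `a`
  is reported back on the rank scale as `alpha = 1/(a-1)`.  The raw
  sample-space estimator (returning `a` itself) is exposed separately as
  `powerlaw_ml_exponent` for fitting i.i.d. samples.

Nonpositive variances inside a fit range truncate it (with a warning);
fewer than 10 usable ranks is an error.

The exponent is compared against the continuity + differentiability
bound `alpha_c = 1 + 2/d` for inputs of embedding dimension `d`
(`alpha_c -> 1` as `d -> inf`): `alpha < 1` means the representation
manifold is neither continuous nor differentiable, `1 < alpha < alpha_c`
continuous but not differentiable, `alpha > alpha_c` both (C+D).  Exact
boundary values are labeled with the weaker class and flagged.

## Cross-validated PCA

`cvpca(repeat1, repeat2)` estimates stimulus-related component variances
from two runs that share the signal (same weights and images) but carry
independent noise streams: both repeats are centered with repeat 1's
unit means, eigenvectors `u_i` come from repeat 1's covariance, and the
signal variance of component `i` is `(1/S)(u_i' X1c)(u_i' X2c)'`.  Noise
independent across repeats cancels in expectation.  Negative estimates
are retained in the output but excluded from power-law fit ranges.  At
desk scale (N = 200, S = 6000) the cvPCA exponent recovers the noiseless
exponent to within ~0.1 for favourable seeds but can deviate by up to
~0.3, because eigenvector estimation noise dominates the deep tail of
the spectrum; the recovery sharpens with the sample count.

## Reservoir model space and readout

Each image's trajectory is summarized by the ridge-fitted linear
one-step model `x(t+1) = W_x x(t) + w_x` over its T-1 transitions;
`theta = [vec(W_x); w_x]` (length `N(N+1)`, row-major vec) is the
classification feature.  The readout `y = W_out theta + w_out` is
ridge-trained against one-hot class targets; the predicted class is the
argmax (ties broken toward the lowest class index).  Both ridge
problems leave the bias unpenalized — solved exactly by centering — and
are computed in closed form (dual form when features outnumber
samples), cross-checked in the tests against scikit-learn's SVD-based
Ridge.  Both penalties default to 1.0 (scale set by the z-scored
features; no values are prescribed by the method itself).  Features are
z-scored per dimension over the training set by default (parameters
frozen for test data; penalties are scale-sensitive), toggleable via
`standardize`.

## Synthetic image generators

The generators emulate the statistical structure the analyses depend on,
not the appearance of any particular dataset:

* **Low-rank images** (`generate_lowrank_images`): `d` spatially smooth,
  orthonormalized random basis patterns combined with i.i.d. Gaussian
  latents, then mapped affinely (global min/max) into [0, 1].  The
  affine map preserves the rank of the centered ensemble, so the
  returned images span exactly `d` dimensions — the only property the
  dimensionality analysis uses.
* **Naturalistic images** (`generate_naturalistic_images`): Gaussian
  random fields with isotropic power spectrum `~ f^(-beta)` and random
  phases (default `beta = 2`, the classic natural-scene slope); DC
  removed, per-image min-max normalization (per-ensemble available).
* **Labeled images** (`generate_labeled_images`): one deterministic
  template per class — an elongated Gaussian blob at a class-specific
  position and orientation on a dark background, echoing the spatial
  sparseness of handwritten digits — plus i.i.d. pixel noise, clipped
  to [0, 1].

What they do *not* emulate: higher-order statistics of natural scenes
(edges, occlusions), stroke-level structure of digits, or correlated
trial-to-trial variability.  Passing tests therefore demonstrate the
pipeline's behavior under controlled second-order statistics, not
performance claims about any real dataset.

## Study conditions (desk scale)

Dynamics and spectrum studies run with N = 200 reservoirs driven by
M = 200 naturalistic 30 x 30 images; classification sweeps with N = 100.
The noisy conditions use `xi = 0.4`.  The 4-class sweep sets the
within-class pixel noise to 0.3 (digit-like within-class variability; at
0.05 the task saturates at 0% error in every regime and cannot resolve
the performance decay) and spans `rho` in {0.3, 0.7, 0.95, 1.3, 1.8,
2.5, 3.5} at `eps = 0.6`, because chaos onset for this generator sits
near `rho ~ 2.3`.  The easy 3-class benchmark keeps noise 0.05.  A
`full_scale_profile` (N = 2000, M = 2800 at 90 x 90; MNIST at N = 500
via the IDX reader) is provided but not exercised by the tests.
`calibrate_edge` locates the operating point by bisecting `rho` (or
`eps`) until the measured MLE lands in [-0.02, 0).

## Reproducibility and numerics

Every experiment is exactly reproducible from its JSON-serializable
config and master seed.  Per-grid-point seeds are derived from the
master seed and the point's own coordinates (not a grid index), so a
point's result is independent of which other grid points are present and
of serial/parallel execution.  Sparse spectral radii are computed with
ARPACK (k = 6 — k = 1 can converge to one member of a complex pair that
is not the true maximum — and a fixed start vector for determinism),
with a dense fallback at small N.  Reservoir construction fails loudly
(degenerate-matrix error) if the sampled matrix cannot realize a
positive spectral radius.

## Known limitations

* The MLE is a single exponent of a non-autonomous system; input-driven
  expansion over finite spans is not distinguished from autonomous
  chaos.
* Desk-scale spectra (200 eigenvalues) make the fitted `alpha` sensitive
  to the rank range; values are comparable within a configuration, not
  across scales.
* cvPCA exponent recovery at desk scale carries seed-level variability
  of up to ~0.3 (see above).
* Leaky units, feedback connections and plastic reservoirs are out of
  scope.
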