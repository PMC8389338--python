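import numpy as np
import pytest

from esnchaos.exceptions import DimensionError, FitError, InsufficientSamplesError
from esnchaos.images import generate_lowrank_images
from esnchaos.reservoir import ReservoirConfig, build_reservoir, run_ensemble
from esnchaos.spectrum import (
    CONTINUOUS_NOT_DIFFERENTIABLE,
    CPLUSD,
    NEITHER,
    classify_manifold,
    compute_eigenspectrum,
    cplusd_threshold,
    cvpca,
    fit_powerlaw,
    powerlaw_ml_exponent,
)


def _activity_with_diagonal_covariance(variances, n_samples=240):
    """Rows with exact sample covariance diag(variances): orthogonal
    zero-mean sinusoids rescaled to exact norms."""
    n = len(variances)
    t = np.arange(n_samples)
    rows = np.array([np.sin(2 * np.pi * (i + 1) * (t + 0.5) / n_samples) for i in range(n)])
    rows -= rows.mean(axis=1, keepdims=True)
    # orthogonalize exactly, then set row norms so cov = diag(variances)
    q, _ = np.linalg.qr(rows.T)
    rows = q.T
    rows -= rows.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(rows.T)  # re-orthogonalize after re-centering
    rows = q.T
    scale = np.sqrt(np.asarray(variances) * n_samples) / np.linalg.norm(rows, axis=1)
    return rows * scale[:, None]


class TestComputeEigenspectrum:
    def test_diagonal_covariance_recovered(self):
        activity = _activity_with_diagonal_covariance([3.0, 2.0, 1.0])
        spec = compute_eigenspectrum(activity)
        assert np.allclose(spec.variances, [3.0, 2.0, 1.0], rtol=1e-8)

    def test_rotation_invariance(self, rng):
        activity = rng.standard_normal((20, 300))
        rotation, _ = np.linalg.qr(rng.standard_normal((20, 20)))
        a = compute_eigenspectrum(activity)
        b = compute_eigenspectrum(rotation @ activity)
        assert np.allclose(a.variances, b.variances, rtol=1e-10, atol=1e-12)

    def test_variance_conservation(self, rng):
        activity = rng.standard_normal((15, 100))
        spec = compute_eigenspectrum(activity)
        centered = activity - activity.mean(axis=1, keepdims=True)
        total = (centered**2).sum() / activity.shape[1]
        assert spec.variances.sum() == pytest.approx(total, rel=1e-10)
        assert np.all(np.diff(spec.variances) <= 1e-12)
        assert np.all(spec.variances >= 0)

    def test_linear_regime_preserves_input_rank(self):
        # with rho=0 and tiny eps the reservoir is a linear map of the
        # input columns; nonzero activity eigenvalues match the rank of
        # the centered projected input (the independent oracle)
        images = generate_lowrank_images(50, 10, 10, d=3, seed=2)
        config = ReservoirConfig(
            n_units=60, spectral_radius=0.0, input_scaling=1e-4, seed=8
        )
        weights = build_reservoir(config, n_inputs=10)
        activity = run_ensemble(weights, images, config)
        spec = compute_eigenspectrum(activity)
        n_nonzero = int(np.sum(spec.variances > 1e-10 * spec.total_variance))
        columns = np.concatenate([img.T for img in images.images], axis=0).T
        projected = 1e-4 * (weights.W_in @ columns)
        projected -= projected.mean(axis=1, keepdims=True)
        s = np.linalg.svd(projected, compute_uv=False)
        # component variances are squared singular values; count on the
        # same relative-variance scale as the activity spectrum
        oracle_rank = int(np.sum(s**2 > 1e-10 * np.sum(s**2)))
        assert n_nonzero == oracle_rank

    def test_too_few_samples_rejected(self):
        with pytest.raises(InsufficientSamplesError):
            compute_eigenspectrum(np.zeros((4, 1)))


class TestFitPowerLaw:
    @pytest.mark.parametrize("alpha0", [1.0, 1.5])
    def test_exact_power_law_regression(self, alpha0):
        variances = np.arange(1, 1001.0) ** (-alpha0)
        fit = fit_powerlaw(variances, rank_range=(1, 1000))
        assert fit.alpha == pytest.approx(alpha0, abs=1e-6)
        assert fit.goodness == pytest.approx(1.0, abs=1e-9)

    def test_clauset_ml_on_iid_samples(self):
        # inverse-CDF samples from p(x) ~ x^(-2.5), x >= 1
        rng = np.random.default_rng(2)
        samples = (1.0 - rng.random(10000)) ** (-1.0 / 1.5)
        a, xmin, ks, m = powerlaw_ml_exponent(samples)
        assert a == pytest.approx(2.5, abs=0.05)
        assert m >= 1000

    def test_clauset_ml_fixed_cutoff(self):
        rng = np.random.default_rng(3)
        samples = (1.0 - rng.random(10000)) ** (-1.0 / 1.5)
        a, xmin, ks, m = powerlaw_ml_exponent(samples, xmin=1.0)
        assert xmin == 1.0 and m == 10000
        assert a == pytest.approx(2.5, abs=0.05)

    @pytest.mark.parametrize("alpha0", [0.8, 1.0, 1.5])
    def test_regression_and_clauset_agree_under_jitter(self, alpha0):
        rng = np.random.default_rng(7)
        ranks = np.arange(1, 1001.0)
        variances = ranks ** (-alpha0) * np.exp(0.1 * rng.standard_normal(1000))
        variances = np.sort(variances)[::-1]  # rank-ordered
        reg = fit_powerlaw(variances, rank_range=(1, 1000))
        ml = fit_powerlaw(variances, method="clauset-ml", rank_range=(1, 1000))
        assert reg.alpha == pytest.approx(alpha0, abs=0.1)
        assert abs(reg.alpha - ml.alpha) < 0.15

    def test_nonpositive_variances_truncate_with_warning(self):
        variances = np.concatenate([np.arange(1, 41.0) ** -1.0, np.zeros(20)])
        with pytest.warns(UserWarning, match="truncating"):
            fit = fit_powerlaw(variances, rank_range=(1, 60))
        assert fit.rank_range == (1, 40)

    def test_too_few_usable_ranks_rejected(self):
        with pytest.raises(FitError):
            fit_powerlaw(np.arange(1, 9.0) ** -1.0, rank_range=(1, 8))


class TestCvPCA:
    def test_identical_repeats_reduce_to_pca(self, rng):
        activity = rng.standard_normal((50, 400))
        cv = cvpca(activity, activity)
        spec = compute_eigenspectrum(activity)
        scale = spec.variances[0]
        assert np.allclose(cv.signal_variances, spec.variances, atol=1e-12 * scale)

    def test_independent_noise_has_zero_mean_signal(self):
        # no shared signal: expected signal variance is 0 per component
        rng = np.random.default_rng(11)
        grand = []
        for _ in range(50):
            a = rng.standard_normal((100, 2000))
            b = rng.standard_normal((100, 2000))
            grand.append(cvpca(a, b).signal_variances.mean())
        assert abs(np.mean(grand)) < 0.01  # Monte-Carlo error band

    def test_signal_recovery_under_noise(self):
        # known signal spectrum s_n = 1/n over 30 dims + white noise;
        # cvPCA recovers the top-20 signal variances within 5% relative
        rng = np.random.default_rng(0)
        n_units, n_signal, n_samples = 100, 30, 5000
        s = np.arange(1, n_signal + 1.0) ** -1.0
        basis, _ = np.linalg.qr(rng.standard_normal((n_units, n_signal)))
        signal = (basis * np.sqrt(s)) @ rng.standard_normal((n_signal, n_samples))
        repeat1 = signal + 0.1 * rng.standard_normal((n_units, n_samples))
        repeat2 = signal + 0.1 * rng.standard_normal((n_units, n_samples))
        estimate = cvpca(repeat1, repeat2).signal_variances[:20]
        assert np.max(np.abs(estimate - s[:20]) / s[:20]) < 0.05

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            cvpca(rng.standard_normal((5, 10)), rng.standard_normal((5, 9)))


class TestManifoldClassification:
    @pytest.mark.parametrize(
        "d,expected", [(4, 1.5), (8, 1.25), (1, 3.0), (np.inf, 1.0)]
    )
    def test_cplusd_threshold(self, d, expected):
        assert cplusd_threshold(d) == expected

    def test_invalid_dimension_rejected(self):
        with pytest.raises(DimensionError):
            cplusd_threshold(0.5)

    @pytest.mark.parametrize(
        "alpha,d,label",
        [
            (0.8, 4, NEITHER),
            (0.8, np.inf, NEITHER),
            (1.3, 4, CONTINUOUS_NOT_DIFFERENTIABLE),
            (1.3, 8, CPLUSD),
            (2.0, 4, CPLUSD),
            (1.05, np.inf, CPLUSD),
        ],
    )
    def test_classification_rule(self, alpha, d, label):
        result = classify_manifold(alpha, d)
        assert result.label == label
        assert not result.boundary

    @pytest.mark.parametrize(
        "alpha,d,label",
        [(1.0, 4, NEITHER), (1.5, 4, CONTINUOUS_NOT_DIFFERENTIABLE)],
    )
    def test_boundaries_get_weaker_class_and_flag(self, alpha, d, label):
        result = classify_manifold(alpha, d)
        assert result.label == label
        assert result.boundary
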