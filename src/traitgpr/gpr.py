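"""Gaussian-process regression with an anisotropic squared-exponential kernel.

This is the retrieval engine: a scikit-learn style estimator implementing
exact GP regression with the ARD (per-dimension length scale) squared
exponential covariance

    k(x_i, x_j) = sigma_s^2 * exp(-1/2 * sum_b [(x_i,b - x_j,b)/sigma_b]^2)

trained by maximizing the log marginal likelihood over log-hyperparameters
with analytic gradients, and predicting through the Cholesky factorization

    L L^T = K + sigma_n^2 I,   alpha = L^T \\ (L \\ y),
    f(x*) = k_*^T alpha,       sigma_f^2(x*) = k(x*,x*) - v^T v,  v = L \\ k_*

The per-pixel deployment exploits exactly this factorization: L, alpha and
the input normalization are precomputed once per model and reused for every
pixel, so prediction is two triangular solves per query.  ``predict_direct``
provides the brute-force matrix-inversion form of the same posterior and
serves as the independent oracle in tests.

Two predictive-variance variants exist in the literature depending on
whether the noise variance is added to the prior self-covariance c_*:
``sigma_variant="latent"`` (default) returns the latent-function variance
k(x*,x*) - v^T v; ``"observation"`` adds sigma_n^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Hyperparams",
    "kernel_ase",
    "ARDGaussianProcessRegressor",
    "train_gpr",
    "factorize",
    "predict_mean",
    "predict_sigma",
    "predict_direct",
    "serialize_model",
    "load_model",
    "save_model",
]

FORMAT_VERSION = "1.0"

# jitter escalation bounds, as fractions of mean(diag K)
_JITTER_START = 1e-10
_JITTER_MAX = 1e-4


@dataclass
class Hyperparams:
    """ARD-SE kernel hyperparameters: output variance, per-dimension length
    scales and observation-noise variance."""

    sigma_s2: float
    length_scales: np.ndarray
    sigma_n2: float

    def __post_init__(self) -> None:
        self.length_scales = np.atleast_1d(np.asarray(self.length_scales, float))
        if self.sigma_s2 <= 0:
            raise ValueError("sigma_s2 must be > 0")
        if (self.length_scales <= 0).any():
            raise ValueError("length scales must be > 0")
        if self.sigma_n2 < 0:
            raise ValueError("sigma_n2 must be >= 0")

    @property
    def n_dims(self) -> int:
        return self.length_scales.size


def kernel_ase(xi: np.ndarray, xj: np.ndarray, theta: Hyperparams) -> float:
    """ARD squared-exponential similarity between two D-vectors."""
    xi = np.asarray(xi, float).ravel()
    xj = np.asarray(xj, float).ravel()
    if xi.size != xj.size or xi.size != theta.n_dims:
        raise ValueError(
            f"dimension mismatch: xi {xi.size}, xj {xj.size}, theta {theta.n_dims}"
        )
    z = (xi - xj) / theta.length_scales
    return float(theta.sigma_s2 * np.exp(-0.5 * np.dot(z, z)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, theta: Hyperparams) -> np.ndarray:
    """Gram matrix between row sets A (n×D) and B (m×D)."""
    As = A / theta.length_scales
    Bs = B / theta.length_scales
    d2 = (
        (As ** 2).sum(axis=1)[:, None]
        + (Bs ** 2).sum(axis=1)[None, :]
        - 2.0 * As @ Bs.T
    )
    return theta.sigma_s2 * np.exp(-0.5 * np.maximum(d2, 0.0))


def _chol_with_jitter(K: np.ndarray, sigma_n2: float) -> tuple[np.ndarray, float]:
    """Cholesky of K + sigma_n2 I with escalating jitter on failure."""
    n = K.shape[0]
    base = K + sigma_n2 * np.eye(n)
    scale = float(np.mean(np.diag(K)))
    jitter = 0.0
    while True:
        try:
            L = cholesky(base + jitter * np.eye(n), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = _JITTER_START * scale if jitter == 0.0 else jitter * 10.0
            if jitter > _JITTER_MAX * scale:
                raise np.linalg.LinAlgError(
                    "covariance not positive definite after maximum jitter"
                )


def factorize(
    X: np.ndarray, y: np.ndarray, theta: Hyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Cholesky factor L of K + sigma_n2 I and weight vector alpha.

    alpha = L^T \\ (L \\ y), i.e. (K + sigma_n2 I)^-1 y computed stably.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    K = _kernel_matrix(X, X, theta)
    L, _ = _chol_with_jitter(K, theta.sigma_n2)
    alpha = cho_solve((L, True), y)
    return L, alpha


class ARDGaussianProcessRegressor(BaseEstimator, RegressorMixin):
    """Exact GP regression with the ARD squared-exponential kernel.

    Parameters
    ----------
    n_restarts : int
        Number of additional seeded restarts of the marginal-likelihood
        optimizer beyond the data-driven initialization.
    sigma_variant : {"latent", "observation"}
        Predictive variance convention: latent-function variance
        k(x*,x*) − vᵀv (default) or with the noise variance added.
    normalize_x, center_y : bool
        Standardize inputs per dimension / subtract the output mean before
        training.  Both are stored on the model and inverted at prediction,
        so they only affect optimizer conditioning, not the learned map.
    init : Hyperparams, optional
        Explicit optimizer initialization (in the normalized input space);
        default derives length scales from per-dimension spread and
        variances from var(y).
    optimize : bool
        If False, ``init`` is used as-is (no marginal-likelihood search).
    random_state : int

    Attributes
    ----------
    X_train_ : (N, D) normalized training inputs
    y_train_ : (N,) centered training outputs
    theta_ : Hyperparams (in normalized input units)
    L_, alpha_ : Cholesky factor and weight vector
    input_mean_, input_scale_ : per-dimension normalization
    output_offset_ : scalar added back to predictions
    log_marginal_likelihood_ : value at the optimum
    """

    def __init__(
        self,
        n_restarts: int = 5,
        sigma_variant: str = "latent",
        normalize_x: bool = True,
        center_y: bool = True,
        init: Hyperparams | None = None,
        optimize: bool = True,
        random_state: int = 0,
    ):
        self.n_restarts = n_restarts
        self.sigma_variant = sigma_variant
        self.normalize_x = normalize_x
        self.center_y = center_y
        self.init = init
        self.optimize = optimize
        self.random_state = random_state

    # ---- marginal likelihood -------------------------------------------

    @staticmethod
    def _lml_and_grad(log_theta: np.ndarray, X: np.ndarray, y: np.ndarray):
        """Log marginal likelihood and gradient w.r.t. log-hyperparameters.

        log_theta = [log sigma_s2, log l_1..l_D, log sigma_n2].
        """
        n, d = X.shape
        sigma_s2 = np.exp(log_theta[0])
        ls = np.exp(log_theta[1 : 1 + d])
        sigma_n2 = np.exp(log_theta[-1])
        theta = Hyperparams(sigma_s2, ls, sigma_n2)
        K = _kernel_matrix(X, X, theta)
        try:
            L, _ = _chol_with_jitter(K, sigma_n2)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros_like(log_theta)
        alpha = cho_solve((L, True), y)
        lml = (
            -0.5 * float(y @ alpha)
            - float(np.log(np.diag(L)).sum())
            - 0.5 * n * np.log(2.0 * np.pi)
        )
        # dlml/dtheta_k = 1/2 tr((alpha alpha^T - K^-1) dK/dtheta_k)
        Kinv = cho_solve((L, True), np.eye(n))
        A = np.outer(alpha, alpha) - Kinv
        grad = np.empty_like(log_theta)
        grad[0] = 0.5 * float((A * K).sum())  # dK/dlog sigma_s2 = K
        for b in range(d):
            d2 = ((X[:, b][:, None] - X[:, b][None, :]) / ls[b]) ** 2
            grad[1 + b] = 0.5 * float((A * (K * d2)).sum())
        grad[-1] = 0.5 * sigma_n2 * float(np.trace(A))
        return lml, grad

    def _default_init(self, X: np.ndarray, y: np.ndarray) -> Hyperparams:
        spread = X.std(axis=0)
        spread[spread == 0] = 1.0
        vy = float(y.var())
        if vy == 0:
            vy = 1.0
        return Hyperparams(vy, spread, 0.01 * vy)

    # ---- estimator API -------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_dims)")
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 2 and self.optimize:
            raise ValueError("need at least 2 training samples to optimize")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in training data")
        if X.shape[0] > 2000:
            warnings.warn(
                "GP training is O(N^3); N > 2000 will be slow and memory-hungry",
                RuntimeWarning,
            )

        if self.normalize_x:
            self.input_mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.input_scale_ = scale
        else:
            self.input_mean_ = np.zeros(X.shape[1])
            self.input_scale_ = np.ones(X.shape[1])
        Xn = (X - self.input_mean_) / self.input_scale_

        self.output_offset_ = float(y.mean()) if self.center_y else 0.0
        yc = y - self.output_offset_
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())

        init = self.init if self.init is not None else self._default_init(Xn, yc)
        if init.n_dims != X.shape[1]:
            raise ValueError("init length_scales do not match n_dims")

        if self.optimize and yc.any():
            theta, lml = self._optimize(Xn, yc, init)
        else:
            theta = Hyperparams(init.sigma_s2, init.length_scales.copy(), init.sigma_n2)
            lml, _ = self._lml_and_grad(self._pack(theta), Xn, yc)

        self.X_train_ = Xn
        self.y_train_ = yc
        self.theta_ = theta
        self.L_, self.alpha_ = factorize(Xn, yc, theta)
        self.log_marginal_likelihood_ = lml
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _pack(theta: Hyperparams) -> np.ndarray:
        return np.concatenate(
            [
                [np.log(theta.sigma_s2)],
                np.log(theta.length_scales),
                [np.log(max(theta.sigma_n2, 1e-12))],
            ]
        )

    def _optimize(self, X, y, init: Hyperparams) -> tuple[Hyperparams, float]:
        rng = np.random.default_rng(self.random_state)
        x0s = [self._pack(init)]
        for _ in range(self.n_restarts):
            x0s.append(x0s[0] + rng.normal(0.0, 1.0, size=x0s[0].size))

        def objective(lt):
            lml, grad = self._lml_and_grad(lt, X, y)
            if not np.isfinite(lml):
                return 1e25, np.zeros_like(lt)
            return -lml, -grad

        bounds = [(-20.0, 20.0)] * x0s[0].size
        best = None
        for x0 in x0s:
            res = minimize(objective, x0, jac=True, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        lt = best.x
        d = X.shape[1]
        theta = Hyperparams(
            float(np.exp(lt[0])), np.exp(lt[1 : 1 + d]), float(np.exp(lt[-1]))
        )
        return theta, -float(best.fun)

    def _normalize_query(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query has {X.shape[1]} dims, model has {self.n_features_in_}"
            )
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in query")
        return (X - self.input_mean_) / self.input_scale_

    def predict(self, X, return_std: bool = False):
        Xq = self._normalize_query(X)
        Ks = _kernel_matrix(Xq, self.X_train_, self.theta_)
        mean = Ks @ self.alpha_ + self.output_offset_
        if not return_std:
            return mean
        v = solve_triangular(self.L_, Ks.T, lower=True)
        var = self.theta_.sigma_s2 - (v ** 2).sum(axis=0)
        if self.sigma_variant == "observation":
            var = var + self.theta_.sigma_n2
        elif self.sigma_variant != "latent":
            raise ValueError(f"unknown sigma_variant {self.sigma_variant!r}")
        return mean, np.sqrt(np.clip(var, 0.0, None))


# ---- thin functional wrappers ------------------------------------------


def train_gpr(
    X,
    y,
    init: Hyperparams | None = None,
    restarts: int = 5,
    seed: int = 0,
    **kwargs,
) -> ARDGaussianProcessRegressor:
    """Fit an :class:`ARDGaussianProcessRegressor` and return it."""
    return ARDGaussianProcessRegressor(
        n_restarts=restarts, init=init, random_state=seed, **kwargs
    ).fit(X, y)


def predict_mean(model: ARDGaussianProcessRegressor, x_star) -> np.ndarray:
    """Posterior mean k_*ᵀ·alpha (+ output offset) at the query point(s)."""
    return model.predict(np.atleast_2d(x_star))


def predict_sigma(model: ARDGaussianProcessRegressor, x_star) -> np.ndarray:
    """Posterior predictive standard deviation at the query point(s)."""
    _, s = model.predict(np.atleast_2d(x_star), return_std=True)
    return s


def predict_direct(
    X,
    y,
    theta: Hyperparams,
    x_star,
    sigma_variant: str = "latent",
    offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force GP posterior via explicit matrix inversion.

    f(x*) = k_*ᵀ (K + σ_n² I)⁻¹ y and σ_f²(x*) = c_* − k_*ᵀ (K + σ_n² I)⁻¹ k_*
    with c_* = k(x*,x*) (latent) or k(x*,x*) + σ_n² (observation).  This is
    numerically worse than the Cholesky path and exists as its test oracle.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xq = np.atleast_2d(np.asarray(x_star, float))
    K = _kernel_matrix(X, X, theta) + theta.sigma_n2 * np.eye(X.shape[0])
    Kinv = np.linalg.inv(K)
    Ks = _kernel_matrix(Xq, X, theta)
    mean = Ks @ (Kinv @ y) + offset
    c_star = theta.sigma_s2 + (theta.sigma_n2 if sigma_variant == "observation" else 0.0)
    var = c_star - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, np.sqrt(np.clip(var, 0.0, None))


# ---- serialization ------------------------------------------------------

_REQUIRED_FIELDS = (
    "format_version",
    "trait",
    "band_ids",
    "input_norm",
    "output_offset",
    "theta",
    "X_train",
    "y_train",
    "L",
    "alpha",
)


def serialize_model(
    model: ARDGaussianProcessRegressor,
    trait: str = "",
    band_ids: list[str] | None = None,
) -> dict:
    """Portable JSON-able document with every precomputed prediction term.

    A loaded document reproduces predictions without re-factorization: the
    normalization, L and alpha are all stored explicitly.
    """
    if band_ids is None:
        band_ids = getattr(model, "band_ids_", None) or [
            f"band_{i + 1:02d}" for i in range(model.n_features_in_)
        ]
    if len(band_ids) != model.n_features_in_:
        raise ValueError("band_ids length does not match model dimensionality")
    return {
        "format_version": FORMAT_VERSION,
        "trait": trait or getattr(model, "trait_", ""),
        "band_ids": list(band_ids),
        "input_norm": {
            "mean": model.input_mean_.tolist(),
            "scale": model.input_scale_.tolist(),
        },
        "output_offset": model.output_offset_,
        "output_range": [model.y_min_, model.y_max_],
        "sigma_variant": model.sigma_variant,
        "theta": {
            "sigma_s2": model.theta_.sigma_s2,
            "length_scales": model.theta_.length_scales.tolist(),
            "sigma_n2": model.theta_.sigma_n2,
        },
        "X_train": model.X_train_.tolist(),
        "y_train": model.y_train_.tolist(),
        "L": model.L_.tolist(),
        "alpha": model.alpha_.tolist(),
    }


def load_model(document: dict) -> ARDGaussianProcessRegressor:
    """Rebuild a fitted model from its serialized document.

    Refuses documents with missing fields, an unknown format version, or a
    band list inconsistent with the stored training matrix.
    """
    missing = [f for f in _REQUIRED_FIELDS if f not in document]
    if missing:
        raise ValueError(f"model document missing fields: {missing}")
    if document["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {document['format_version']!r}"
        )
    X = np.asarray(document["X_train"], float)
    if len(document["band_ids"]) != X.shape[1]:
        raise ValueError(
            f"band_ids has {len(document['band_ids'])} entries but X_train has "
            f"{X.shape[1]} columns"
        )
    th = document["theta"]
    model = ARDGaussianProcessRegressor(
        sigma_variant=document.get("sigma_variant", "latent")
    )
    model.X_train_ = X
    model.y_train_ = np.asarray(document["y_train"], float)
    model.theta_ = Hyperparams(
        th["sigma_s2"], np.asarray(th["length_scales"], float), th["sigma_n2"]
    )
    model.L_ = np.asarray(document["L"], float)
    model.alpha_ = np.asarray(document["alpha"], float)
    model.input_mean_ = np.asarray(document["input_norm"]["mean"], float)
    model.input_scale_ = np.asarray(document["input_norm"]["scale"], float)
    model.output_offset_ = float(document["output_offset"])
    rng = document.get("output_range", [0.0, 1.0])
    model.y_min_, model.y_max_ = float(rng[0]), float(rng[1])
    model.n_features_in_ = X.shape[1]
    model.trait_ = document["trait"]
    model.band_ids_ = list(document["band_ids"])
    model.log_marginal_likelihood_ = document.get("log_marginal_likelihood", np.nan)
    return model


def save_model(model, path, trait: str = "", band_ids=None) -> None:
    with open(path, "w") as fh:
        json.dump(serialize_model(model, trait=trait, band_ids=band_ids), fh)


def load_model_file(path) -> ARDGaussianProcessRegressor:
    with open(path) as fh:
        return load_model(json.load(fh))
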