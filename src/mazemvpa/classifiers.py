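"""Binary classifiers: soft-margin linear SVM and GP classification with EP.

The SVM is the standard C-SVC with a linear kernel and fixed C = 1, solved
by libsvm (through scikit-learn); the model object exposes the primal weight
vector, the support-vector set and the dual coefficients, which downstream
code uses both for weight-based feature ranking and for support-vector
class-proportion diagnostics.

The Gaussian-process classifier places a zero-mean GP prior with an
inhomogeneous linear covariance k(x, x') = sigma^2 <x, x'> + sigma0^2 over
the latent function (both terms tied to the single hyperparameter sigma,
i.e. sigma0^2 = sigma^2), squashes the latent through a probit likelihood,
and approximates the non-Gaussian posterior with Expectation Propagation:
iterative moment matching of Gaussian "site" approximations, which for the
probit likelihood has closed-form cavity moments.  Kernel matrices are
centered before training and, following the same convention, the test
kernel blocks are centered independently of the training block.  The
EP approximate log marginal likelihood is available and is maximized over
log(sigma) by default (initialized at 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import log_ndtr, ndtr
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "SVMModel",
    "GPModel",
    "linear_kernel_inhom",
    "center_kernel",
    "center_test_kernel",
    "train_linear_svm",
    "svm_predict",
    "sv_class_proportions",
    "gp_ep_train",
    "gp_predict_prob",
]


# ---------------------------------------------------------------------------
# kernels


@dataclass(frozen=True)
class KernelSpec:
    """Inhomogeneous linear kernel hyperparameters.

    ``sigma`` scales the prior covariance (Sigma_p = sigma^2 I) and, unless
    ``sigma0_sq`` is given explicitly, also the bias term sigma0^2 = sigma^2.
    ``centering`` chooses how the test-vs-train kernel block is centered:
    "independent" (each block double-centered with its own means) or "train"
    (the conventional centering with training-set statistics).
    """

    sigma: float = float(np.e)
    sigma0_sq: float | None = None
    centering: str = "independent"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.centering not in ("independent", "train", "none"):
            raise ValueError(f"unknown centering mode {self.centering!r}")

    @property
    def bias(self) -> float:
        return self.sigma**2 if self.sigma0_sq is None else self.sigma0_sq


def linear_kernel_inhom(X1, X2, spec: KernelSpec = KernelSpec()) -> np.ndarray:
    """K[i, j] = sigma^2 <x1_i, x2_j> + sigma0^2."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"dimension mismatch: {X1.shape[1]} vs {X2.shape[1]} features"
        )
    return spec.sigma**2 * (X1 @ X2.T) + spec.bias


def center_kernel(K: np.ndarray) -> np.ndarray:
    """Double-center a kernel matrix using its own row/column means.

    Equivalent, for a square kernel, to H K H with H = I - (1/n) 11'.
    Idempotent; applies to rectangular blocks as well ("independent" mode).
    """
    K = np.asarray(K, dtype=float)
    return K - K.mean(axis=1, keepdims=True) - K.mean(axis=0, keepdims=True) + K.mean()


def center_test_kernel(
    K_test_train: np.ndarray, K_train: np.ndarray, mode: str = "independent"
) -> np.ndarray:
    """Center the test-vs-train kernel block.

    "independent" double-centers the block with its own means; "train" uses
    training-set statistics (the conventional feature-space centering)."""
    if mode == "independent":
        return center_kernel(K_test_train)
    if mode == "train":
        K_test_train = np.asarray(K_test_train, dtype=float)
        K_train = np.asarray(K_train, dtype=float)
        col = K_train.mean(axis=0, keepdims=True)
        row = K_test_train.mean(axis=1, keepdims=True)
        return K_test_train - row - col + K_train.mean()
    if mode == "none":
        return np.asarray(K_test_train, dtype=float)
    raise ValueError(f"unknown centering mode {mode!r}")


# ---------------------------------------------------------------------------
# SVM


@dataclass
class SVMModel:
    """Fitted linear C-SVC in the +1/-1 label convention."""

    w: np.ndarray
    b: float
    support: np.ndarray
    dual_coef: np.ndarray  # alpha_i * y_i for the support vectors
    C: float
    y_train: np.ndarray


def train_linear_svm(X, y, C: float = 1.0) -> SVMModel:
    """Soft-margin linear SVM (libsvm dual), labels in {-1, +1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        raise ValueError("labels must be coded -1/+1")
    # the iteration cap only binds on degenerate inputs (e.g. zero-variance
    # features under permuted labels), where SMO can cycle without progress
    clf = SVC(kernel="linear", C=C, max_iter=200_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    # classes_ is sorted as [-1, 1], so the decision function is w.x + b with
    # positive values mapping to +1
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    return SVMModel(
        w=w,
        b=b,
        support=clf.support_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        C=C,
        y_train=y,
    )


def svm_predict(model: SVMModel, X) -> np.ndarray:
    """Sign of the decision function; exactly zero maps to +1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    score = X @ model.w + model.b
    return np.where(score >= 0, 1, -1)


def sv_class_proportions(model: SVMModel, labels=None) -> dict:
    """Fraction of the support vectors contributed by each class."""
    y = model.y_train if labels is None else np.asarray(labels)
    sv_labels = y[model.support]
    total = len(sv_labels)
    return {c: float(np.sum(sv_labels == c)) / total for c in np.unique(y)}


# ---------------------------------------------------------------------------
# GP with Expectation Propagation


@dataclass
class GPModel:
    """EP-fitted binary GP classifier.

    Site parameters (tau_site >= 0, nu_site) define the Gaussian
    approximations to the probit likelihood factors; ``log_marginal`` is the
    EP approximation to log p(y | X, sigma).
    """

    X_train: np.ndarray
    y: np.ndarray
    spec: KernelSpec
    tau_site: np.ndarray
    nu_site: np.ndarray
    K: np.ndarray
    log_marginal: float
    converged: bool
    n_sweeps: int
    final_delta: float
    jitter: float = 1e-8
    # cached prediction quantities
    _alpha: np.ndarray | None = field(default=None, repr=False)
    _L: np.ndarray | None = field(default=None, repr=False)
    _sqrt_tau: np.ndarray | None = field(default=None, repr=False)


def _ep_sweeps(K: np.ndarray, y: np.ndarray, tol: float, max_sweeps: int):
    """Sequential EP for probit-likelihood GP classification.

    Standard moment-matching site updates with rank-one posterior updates
    and a full Cholesky recomputation after every sweep for stability.
    Returns (tau_site, nu_site, Sigma, mu, converged, n_sweeps, max_delta).
    """
    n = len(y)
    tau = np.zeros(n)
    nu = np.zeros(n)
    Sigma = K.copy()
    mu = np.zeros(n)
    converged = False
    sweep = 0
    max_delta = np.inf
    for sweep in range(1, max_sweeps + 1):
        max_delta = 0.0
        for i in range(n):
            s_ii = Sigma[i, i]
            tau_cav = 1.0 / s_ii - tau[i]
            nu_cav = mu[i] / s_ii - nu[i]
            if tau_cav <= 1e-12:
                continue  # cavity would be improper; skip this site
            sig2_cav = 1.0 / tau_cav
            mu_cav = nu_cav * sig2_cav
            denom = np.sqrt(1.0 + sig2_cav)
            z = y[i] * mu_cav / denom
            ratio = np.exp(_log_npdf(z) - log_ndtr(z))
            mu_hat = mu_cav + y[i] * sig2_cav * ratio / denom
            sig2_hat = sig2_cav - sig2_cav**2 * ratio * (z + ratio) / (1.0 + sig2_cav)
            sig2_hat = max(sig2_hat, 1e-12)
            tau_new = max(1.0 / sig2_hat - tau_cav, 0.0)
            nu_new = mu_hat / sig2_hat - nu_cav
            d_tau = tau_new - tau[i]
            d_nu = nu_new - nu[i]
            tau[i], nu[i] = tau_new, nu_new
            max_delta = max(max_delta, abs(d_tau), abs(d_nu))
            # rank-one posterior update
            s_col = Sigma[:, i].copy()
            Sigma -= (d_tau / (1.0 + d_tau * s_ii)) * np.outer(s_col, s_col)
            mu = Sigma @ nu
        if not np.all(np.isfinite(tau)) or not np.all(np.isfinite(nu)):
            raise FloatingPointError(
                "EP diverged: non-finite site parameters "
                f"(sweep {sweep}, max tau {np.nanmax(tau):.3g})"
            )
        Sigma, mu = _posterior_from_sites(K, tau, nu)
        if max_delta < tol:
            converged = True
            break
    return tau, nu, Sigma, mu, converged, sweep, max_delta


def _log_npdf(z):
    return -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)


def _posterior_from_sites(K, tau, nu):
    """Recompute (Sigma, mu) from the site parameters via Cholesky."""
    n = len(tau)
    s = np.sqrt(tau)
    B = np.eye(n) + (s[:, None] * K) * s[None, :]
    L = cholesky(B, lower=True)
    V = solve_triangular(L, s[:, None] * K, lower=True)
    Sigma = K - V.T @ V
    return Sigma, Sigma @ nu


def _ep_log_marginal(K, y, tau, nu) -> float:
    """EP approximate log marginal likelihood (numerically robust form)."""
    n = len(y)
    s = np.sqrt(tau)
    B = np.eye(n) + (s[:, None] * K) * s[None, :]
    L = cholesky(B, lower=True)
    V = solve_triangular(L, s[:, None] * K, lower=True)
    Sigma = K - V.T @ V
    mu = Sigma @ nu
    d = np.diag(Sigma)
    tau_cav = 1.0 / d - tau
    nu_cav = mu / d - nu
    if np.any(tau_cav <= 0):
        tau_cav = np.maximum(tau_cav, 1e-12)
    mu_cav = nu_cav / tau_cav
    sig2_cav = 1.0 / tau_cav
    z = y * mu_cav / np.sqrt(1.0 + sig2_cav)
    lZ_sites = float(np.sum(log_ndtr(z)))
    nlz = (
        float(np.sum(np.log(np.diag(L))))
        - lZ_sites
        - 0.5 * float(nu @ (Sigma @ nu))
        - 0.5 * float(
            nu_cav @ ((tau / tau_cav * nu_cav - 2.0 * nu) / (tau + tau_cav))
        )
        + 0.5 * float(np.sum(nu**2 / (tau_cav + tau)))
        - 0.5 * float(np.sum(np.log1p(tau / tau_cav)))
    )
    return -nlz


def _train_kernel(X: np.ndarray, spec: KernelSpec, jitter: float) -> np.ndarray:
    K = linear_kernel_inhom(X, X, spec)
    if spec.centering != "none":
        K = center_kernel(K)
    return K + jitter * np.eye(len(K))


def gp_ep_train(
    X,
    y,
    spec: KernelSpec = KernelSpec(),
    optimize_sigma: bool = True,
    tol: float = 1e-4,
    max_sweeps: int = 100,
    jitter: float = 1e-8,
) -> GPModel:
    """Fit the binary GP classifier by Expectation Propagation.

    EP iterates until the largest site-parameter change in a sweep falls
    below ``tol`` (or ``max_sweeps`` is reached, recorded as non-converged).
    When ``optimize_sigma`` is set, sigma is refined by maximizing the EP
    log marginal likelihood over log(sigma), starting from the
    log(sigma) = 1 initialization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        raise ValueError("labels must be coded -1/+1")

    # with sigma0^2 tied to sigma^2 the centered kernel is sigma^2 * K0, so
    # the base kernel can be computed once and rescaled during optimization
    base_spec = KernelSpec(sigma=1.0, sigma0_sq=None, centering=spec.centering)
    K0 = _train_kernel(X, base_spec, jitter=0.0)

    def fit_at(log_sigma: float):
        sig2 = np.exp(2.0 * log_sigma)
        K = sig2 * K0 + jitter * np.eye(len(K0))
        tau, nu, _Sigma, _mu, conv, sweeps, delta = _ep_sweeps(K, y, tol, max_sweeps)
        lml = _ep_log_marginal(K, y, tau, nu)
        return K, tau, nu, conv, sweeps, delta, lml

    log_sigma = float(np.log(spec.sigma))
    if optimize_sigma:
        def objective(ls):
            try:
                return -fit_at(ls)[-1]
            except (FloatingPointError, np.linalg.LinAlgError):
                return np.inf

        res = optimize.minimize_scalar(
            objective,
            bounds=(log_sigma - 4.0, log_sigma + 4.0),
            method="bounded",
            options={"maxiter": 12, "xatol": 0.05},
        )
        if np.isfinite(res.fun) and res.fun < objective(log_sigma):
            log_sigma = float(res.x)

    K, tau, nu, conv, sweeps, delta, lml = fit_at(log_sigma)
    final_spec = KernelSpec(
        sigma=float(np.exp(log_sigma)), sigma0_sq=spec.sigma0_sq,
        centering=spec.centering,
    )
    model = GPModel(
        X_train=X,
        y=y,
        spec=final_spec,
        tau_site=tau,
        nu_site=nu,
        K=K,
        log_marginal=lml,
        converged=conv,
        n_sweeps=sweeps,
        final_delta=delta,
        jitter=jitter,
    )
    _cache_prediction_terms(model)
    return model


def _cache_prediction_terms(model: GPModel) -> None:
    n = len(model.y)
    s = np.sqrt(model.tau_site)
    B = np.eye(n) + (s[:, None] * model.K) * s[None, :]
    L = cholesky(B, lower=True)
    t = cho_solve((L, True), s * (model.K @ model.nu_site))
    model._alpha = model.nu_site - s * t
    model._L = L
    model._sqrt_tau = s


def gp_predict_prob(model: GPModel, X_test) -> np.ndarray:
    """Predictive probability of the +1 class for each test point.

    The latent predictive mean and variance follow from the EP posterior;
    pushing them through the probit gives probabilities strictly inside
    (0, 1).  Test kernel blocks are centered according to the model's
    centering mode.
    """
    if not model.converged:
        warnings.warn(
            f"EP did not converge (last max site change {model.final_delta:.2e}); "
            "predictive probabilities may be inaccurate",
            stacklevel=2,
        )
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    spec = model.spec
    Ks_raw = linear_kernel_inhom(X_test, model.X_train, spec)
    Kss_raw = linear_kernel_inhom(X_test, X_test, spec)
    if spec.centering == "none":
        Ks, Kss_diag = Ks_raw, np.diag(Kss_raw).copy()
    elif spec.centering == "independent":
        Ks = center_kernel(Ks_raw)
        Kss_diag = np.diag(center_kernel(Kss_raw)).copy()
    else:  # train-statistics centering
        K_train_raw = linear_kernel_inhom(model.X_train, model.X_train, spec)
        Ks = center_test_kernel(Ks_raw, K_train_raw, mode="train")
        col = K_train_raw.mean()
        Kss_diag = (
            np.diag(Kss_raw)
            - 2.0 * Ks_raw.mean(axis=1)
            + col
        )
    f_mean = Ks @ model._alpha
    v = solve_triangular(model._L, model._sqrt_tau[:, None] * Ks.T, lower=True)
    f_var = np.maximum(Kss_diag - np.sum(v**2, axis=0), 1e-12)
    p = ndtr(f_mean / np.sqrt(1.0 + f_var))
    eps = 1e-12
    return np.clip(p, eps, 1.0 - eps)
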