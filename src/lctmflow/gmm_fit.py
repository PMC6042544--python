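"""Maximum-likelihood estimation of latent class trajectory models.

The model: subject ``i`` belongs to latent class ``k`` with probability
``pi_k``; conditional on class, the outcome vector is marginally Gaussian,

    y_i | class k  ~  N( X_i beta_k,  V_ik ),
    V_ik = Z_i B_k Z_i' + sigma_k^2 I,

where ``B_k`` is the random-effects covariance dictated by the structure
code (absent for A/B, one shared matrix for C-E, ``omega_k^2 B`` for F,
unrestricted per class for G) and ``sigma_k^2`` is class-specific only for
structure B.  The observed-data log-likelihood is

    l = sum_i log sum_k pi_k phi(y_i; X_i beta_k, V_ik),

maximised by EM: the E-step computes posterior class probabilities
``p_ik`` in log space; the M-step updates ``pi`` in closed form, ``beta_k``
by posterior-weighted generalised least squares, and the covariance
parameters by a warm-started quasi-Newton ascent of the expected
complete-data objective in a log-Cholesky parameterisation (which keeps
every covariance positive definite).  Because each conditional update can
only increase the expected objective, the observed log-likelihood is
non-decreasing across iterations (generalised EM); the covariance step
keeps its previous value whenever the inner optimiser fails to improve it,
so the monotonicity contract survives numerical noise.

Subjects sharing a visit-time pattern share ``V_ik``, so all dense linear
algebra is factorised once per (pattern, class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.linalg import cholesky as sp_cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .data_model import (
    ConfigurationError,
    DataError,
    FittedModel,
    ModelStructure,
    SufficientSummaries,
    TrajectoryDataset,
    build_design,
    count_parameters,
)

__all__ = [
    "FitConfig",
    "NumericalError",
    "NonConvergenceError",
    "MixtureParams",
    "marginal_covariance",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit",
    "bic",
]

_LOG2PI = math.log(2.0 * math.pi)


class NumericalError(RuntimeError):
    """A covariance became singular/non-PSD beyond what ridge jitter absorbs."""


class NonConvergenceError(RuntimeError):
    """Every EM start failed, or a quantity needing a converged fit was requested."""


@dataclass(frozen=True)
class FitConfig:
    """Convergence and reproducibility machinery for :func:`fit`.

    ``tol`` is the relative log-likelihood change that declares
    convergence; ``ridge`` is a diagonal jitter added to every marginal
    covariance before factorisation; ``cov_maxiter`` caps the inner
    quasi-Newton iterations of the covariance M-step (the warm start makes
    a handful sufficient); classes whose mixing proportion falls below
    ``min_class_prop_warn`` are flagged, never deleted.
    """

    n_starts: int = 20
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    ridge: float = 1e-8
    min_class_prop_warn: float = 0.005
    cov_maxiter: int = 25

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be > 0")


# --------------------------------------------------------------------------
# Parameter container used during estimation
# --------------------------------------------------------------------------

@dataclass
class MixtureParams:
    """All free parameters of one candidate model, Cholesky-parameterised.

    ``L`` is the lower Cholesky factor of the shared random-effects
    covariance ``B = L L'`` (structures C-F); ``L_by_class`` holds one
    factor per class for G; ``omega`` the proportional class scales for F
    (last entry pinned to 1 for identifiability); ``sigma2`` has one entry,
    or one per class for structure B.
    """

    structure: ModelStructure
    beta: np.ndarray                  # (K, d+1)
    pi: np.ndarray                    # (K,)
    L: np.ndarray | None = None       # (q, q) lower triangular
    omega: np.ndarray | None = None   # (K,)
    L_by_class: np.ndarray | None = None  # (K, q, q)
    sigma2: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    @property
    def n_classes(self) -> int:
        return self.structure.n_classes

    @property
    def B(self) -> np.ndarray | None:
        return None if self.L is None else self.L @ self.L.T

    @property
    def B_by_class(self) -> np.ndarray | None:
        if self.L_by_class is None:
            return None
        return np.einsum("kij,klj->kil", self.L_by_class, self.L_by_class)

    def class_random_cov(self, k: int) -> np.ndarray:
        q = self.structure.n_random
        mode = self.structure.random_cov_mode
        if mode == "none":
            return np.zeros((q, q))
        if mode == "shared":
            return self.B
        if mode == "proportional":
            return self.omega[k] ** 2 * self.B
        return self.B_by_class[k]

    def class_sigma2(self, k: int) -> float:
        if self.structure.residual_mode == "by_class":
            return float(self.sigma2[k])
        return float(self.sigma2[0])


def marginal_covariance(params, Z: np.ndarray, k: int, ridge: float = 0.0) -> np.ndarray:
    """Marginal covariance ``V_ik = Z B_k Z' + sigma_k^2 I`` for class ``k``.

    ``params`` may be a :class:`MixtureParams` or a fitted model — anything
    exposing ``class_random_cov`` and ``class_sigma2``.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    Bk = params.class_random_cov(k)
    V = Z @ Bk @ Z.T if Bk.size else np.zeros((n, n))
    V = 0.5 * (V + V.T)
    V[np.diag_indices(n)] += params.class_sigma2(k) + ridge
    return V


def _chol(V: np.ndarray, k: int) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"marginal covariance of class {k} is not positive definite") from exc


# --------------------------------------------------------------------------
# Log densities, likelihood, E-step
# --------------------------------------------------------------------------

def _log_densities(params: MixtureParams, design: SufficientSummaries,
                   ridge: float = 1e-8) -> np.ndarray:
    """``(N, K)`` matrix of log phi(y_i; X_i beta_k, V_ik)."""
    K = params.n_classes
    N = design.n_subjects
    logden = np.empty((N, K))
    shared_V = params.structure.random_cov_mode in ("none", "shared") \
        and params.structure.residual_mode == "common"
    for g in design.pattern_groups:
        X, Z, Y, idx = g["X"], g["Z"], g["Y"], g["idx"]
        n = X.shape[0]
        cho = None
        for k in range(K):
            if cho is None or not shared_V:
                V = marginal_covariance(params, Z, k, ridge=ridge)
                cho = _chol(V, k)
                logdet = 2.0 * np.log(np.diag(cho)).sum()
            R = Y - X @ params.beta[k]              # (m, n)
            A = solve_triangular(cho, R.T, lower=True)
            quad = np.einsum("ij,ij->j", A, A)
            logden[idx, k] = -0.5 * (n * _LOG2PI + logdet + quad)
    return logden


def _loglik_and_posterior(params: MixtureParams, design: SufficientSummaries,
                          ridge: float = 1e-8):
    logden = _log_densities(params, design, ridge=ridge)
    logpi = np.log(np.maximum(params.pi, 1e-300))
    lw = logden + logpi
    lse = logsumexp(lw, axis=1)
    flagged = np.where(~np.isfinite(lse))[0]
    post = np.exp(lw - lse[:, None])
    if flagged.size:
        post[flagged] = params.pi  # no information: fall back to the prior
        lse = np.where(np.isfinite(lse), lse, -745.0)  # ~log(min double)
    post /= post.sum(axis=1, keepdims=True)
    return float(lse.sum()), post, flagged


def log_likelihood(params, data: SufficientSummaries | TrajectoryDataset,
                   ridge: float = 1e-8) -> float:
    """Observed-data mixture log-likelihood ``l`` at the given parameters."""
    design = _as_design(data, params.structure)
    ll, _, _ = _loglik_and_posterior(_as_params(params), design, ridge=ridge)
    return ll


def e_step(params, data: SufficientSummaries | TrajectoryDataset,
           ridge: float = 1e-8) -> np.ndarray:
    """Posterior class probabilities ``p_ik``; every row sums to 1."""
    design = _as_design(data, params.structure)
    _, post, _ = _loglik_and_posterior(_as_params(params), design, ridge=ridge)
    return post


def _as_design(data, structure: ModelStructure) -> SufficientSummaries:
    if isinstance(data, TrajectoryDataset):
        return build_design(data, structure)
    return data


def _as_params(params) -> MixtureParams:
    if isinstance(params, MixtureParams):
        return params
    # FittedModel (or equivalent): rebuild the Cholesky parameterisation
    s = params.structure
    q = s.n_random
    L = omega = L_by = None
    if s.random_cov_mode in ("shared", "proportional"):
        L = sp_cholesky(params.B + 1e-12 * np.eye(q), lower=True)
    if s.random_cov_mode == "proportional":
        omega = np.asarray(params.omega, dtype=float)
    if s.random_cov_mode == "by_class":
        L_by = np.stack([sp_cholesky(params.B_by_class[k] + 1e-12 * np.eye(q), lower=True)
                         for k in range(s.n_classes)])
    return MixtureParams(structure=s, beta=np.asarray(params.beta, dtype=float),
                         pi=np.asarray(params.pi, dtype=float), L=L, omega=omega,
                         L_by_class=L_by, sigma2=np.atleast_1d(np.asarray(params.sigma2,
                                                                          dtype=float)))


# --------------------------------------------------------------------------
# Covariance M-step: log-Cholesky parameterisation with analytic gradients
# --------------------------------------------------------------------------

def _tri_indices(q: int):
    return np.tril_indices(q)


def _pack_chol(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    r, c = _tri_indices(q)
    v = L[r, c].copy()
    diag = r == c
    v[diag] = np.log(np.maximum(L[np.arange(q), np.arange(q)], 1e-154))
    return v


def _unpack_chol(v: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    r, c = _tri_indices(q)
    L[r, c] = v
    d = np.arange(q)
    L[d, d] = np.exp(np.clip(L[d, d], -300, 300))
    return L


def _chol_grad(dQ_dB: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Gradient wrt the packed log-Cholesky vector, given symmetric dQ/dB."""
    G = 2.0 * dQ_dB @ L
    q = L.shape[0]
    r, c = _tri_indices(q)
    g = G[r, c].copy()
    diag = r == c
    g[diag] = G[np.arange(q), np.arange(q)] * np.diag(L)
    return g


def _pack_theta(params: MixtureParams) -> np.ndarray:
    s = params.structure
    parts = []
    if s.random_cov_mode in ("shared", "proportional"):
        parts.append(_pack_chol(params.L))
    elif s.random_cov_mode == "by_class":
        for k in range(s.n_classes):
            parts.append(_pack_chol(params.L_by_class[k]))
    if s.random_cov_mode == "proportional" and s.n_classes > 1:
        parts.append(np.log(params.omega[:-1]))
    parts.append(np.log(params.sigma2))
    return np.concatenate(parts)


def _unpack_theta(theta: np.ndarray, structure: ModelStructure):
    q = structure.n_random
    K = structure.n_classes
    tri = q * (q + 1) // 2
    pos = 0
    L = omega = L_by = None
    if structure.random_cov_mode in ("shared", "proportional"):
        L = _unpack_chol(theta[pos:pos + tri], q)
        pos += tri
    elif structure.random_cov_mode == "by_class":
        L_by = np.stack([_unpack_chol(theta[pos + k * tri:pos + (k + 1) * tri], q)
                         for k in range(K)])
        pos += K * tri
    if structure.random_cov_mode == "proportional":
        omega = np.ones(K)
        if K > 1:
            omega[:-1] = np.exp(np.clip(theta[pos:pos + K - 1], -300, 300))
            pos += K - 1
    n_sig = K if structure.residual_mode == "by_class" else 1
    sigma2 = np.exp(np.clip(theta[pos:pos + n_sig], -600, 600))
    return L, omega, L_by, sigma2


def _cov_objective(theta: np.ndarray, stats: list[dict], structure: ModelStructure,
                   ridge: float):
    """Negative expected complete-data objective (covariance part) + gradient.

    ``stats`` holds, per visit-time pattern ``g``: the random design ``Z``,
    posterior masses ``W[k]`` and weighted residual scatter ``S[k]``
    (``sum_i p_ik r_ik r_ik'``), with classes pre-summed when the marginal
    covariance does not depend on the class (structures C-E).
    """
    L, omega, L_by, sigma2 = _unpack_theta(theta, structure)
    K = stats[0]["W"].shape[0]
    q = structure.n_random
    Q = 0.0
    gB = np.zeros((q, q))
    gB_by = np.zeros((K, q, q)) if L_by is not None else None
    g_logomega = np.zeros(K) if omega is not None else None
    g_logsig = np.zeros_like(sigma2)
    B = None if L is None else L @ L.T
    for g in stats:
        Z = g["Z"]
        n = Z.shape[0]
        ZBZ = None if B is None else Z @ B @ Z.T
        for k in range(K):
            W = g["W"][k]
            S = g["S"][k]
            if W <= 0 and not np.any(S):
                continue
            c_k = 1.0 if omega is None else omega[k] ** 2
            if L_by is not None:
                Bk = L_by[k] @ L_by[k].T
                Vr = Z @ Bk @ Z.T
            elif ZBZ is not None:
                Vr = c_k * ZBZ
            else:
                Vr = np.zeros((n, n))
            sig = sigma2[k] if sigma2.shape[0] == K else sigma2[0]
            V = Vr + (sig + ridge) * np.eye(n)
            try:
                cho = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros_like(theta)
            logdet = 2.0 * np.log(np.diag(cho)).sum()
            Vi = solve_triangular(cho, np.eye(n), lower=True)
            Vinv = Vi.T @ Vi
            ViS = Vinv @ S
            Q += -0.5 * (W * (n * _LOG2PI + logdet) + np.trace(ViS))
            Gmat = 0.5 * (ViS @ Vinv - W * Vinv)       # dQ/dV, symmetric
            sidx = k if sigma2.shape[0] == K else 0
            g_logsig[sidx] += np.trace(Gmat) * sigma2[sidx]
            if q:
                M = Z.T @ Gmat @ Z                      # dQ/dB_k_eff
                if L_by is not None:
                    gB_by[k] += M
                elif B is not None:
                    gB += c_k * M
                    if omega is not None:
                        g_logomega[k] += 2.0 * c_k * np.sum(M * B)
    # assemble packed gradient
    parts = []
    if structure.random_cov_mode in ("shared", "proportional"):
        parts.append(_chol_grad(0.5 * (gB + gB.T), L))
    elif structure.random_cov_mode == "by_class":
        for k in range(K):
            parts.append(_chol_grad(0.5 * (gB_by[k] + gB_by[k].T), L_by[k]))
    if omega is not None and K > 1:
        parts.append(g_logomega[:-1])
    parts.append(g_logsig)
    grad = np.concatenate(parts)
    return -Q, -grad


def _collect_stats(posterior: np.ndarray, beta: np.ndarray,
                   design: SufficientSummaries, collapse_classes: bool) -> list[dict]:
    K = beta.shape[0]
    stats = []
    for g in design.pattern_groups:
        X, Z, Y, idx = g["X"], g["Z"], g["Y"], g["idx"]
        n = X.shape[0]
        P = posterior[idx]                       # (m, K)
        W = P.sum(axis=0)                        # (K,)
        S = np.empty((K, n, n))
        for k in range(K):
            R = Y - X @ beta[k]
            S[k] = (R * P[:, k][:, None]).T @ R
        if collapse_classes:
            W = np.array([W.sum()])
            S = S.sum(axis=0, keepdims=True)
        stats.append({"Z": Z, "W": W, "S": S})
    return stats


def _update_covariances(params: MixtureParams, posterior: np.ndarray,
                        design: SufficientSummaries, config: FitConfig) -> MixtureParams:
    s = params.structure
    if s.random_cov_mode == "none":
        # closed-form residual variance(s)
        stats = _collect_stats(posterior, params.beta, design, collapse_classes=False)
        K = s.n_classes
        if s.residual_mode == "by_class":
            num = np.zeros(K)
            den = np.zeros(K)
            for g in stats:
                n = g["Z"].shape[0] if g["Z"].size else g["S"].shape[1]
                num += np.trace(g["S"], axis1=1, axis2=2)
                den += g["W"] * g["S"].shape[1]
            sigma2 = np.maximum(num / np.maximum(den, 1e-12), 1e-12)
        else:
            num = sum(np.trace(g["S"], axis1=1, axis2=2).sum() for g in stats)
            den = sum(g["W"].sum() * g["S"].shape[1] for g in stats)
            sigma2 = np.array([max(num / max(den, 1e-12), 1e-12)])
        return replace(params, sigma2=sigma2)
    collapse = s.random_cov_mode == "shared" and s.residual_mode == "common"
    stats = _collect_stats(posterior, params.beta, design, collapse_classes=collapse)
    theta0 = _pack_theta(params)
    f0, _ = _cov_objective(theta0, stats, s, config.ridge)
    res = optimize.minimize(_cov_objective, theta0, args=(stats, s, config.ridge),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": config.cov_maxiter, "ftol": 1e-12})
    theta = res.x if np.isfinite(res.fun) and res.fun <= f0 else theta0
    L, omega, L_by, sigma2 = _unpack_theta(theta, s)
    return replace(params, L=L, omega=omega, L_by_class=L_by,
                   sigma2=np.maximum(sigma2, 1e-12))


# --------------------------------------------------------------------------
# M-step
# --------------------------------------------------------------------------

def _update_beta(params: MixtureParams, posterior: np.ndarray,
                 design: SufficientSummaries, config: FitConfig) -> np.ndarray:
    """Posterior-weighted GLS for each class, under current covariances."""
    K = params.n_classes
    p = params.beta.shape[1]
    A = np.zeros((K, p, p))
    b = np.zeros((K, p))
    shared_V = params.structure.random_cov_mode in ("none", "shared") \
        and params.structure.residual_mode == "common"
    for g in design.pattern_groups:
        X, Z, Y, idx = g["X"], g["Z"], g["Y"], g["idx"]
        P = posterior[idx]
        Vinv = None
        for k in range(K):
            if Vinv is None or not shared_V:
                V = marginal_covariance(params, Z, k, ridge=config.ridge)
                cho = _chol(V, k)
                Vi = solve_triangular(cho, np.eye(V.shape[0]), lower=True)
                Vinv = Vi.T @ Vi
            XtVi = X.T @ Vinv
            A[k] += P[:, k].sum() * (XtVi @ X)
            b[k] += XtVi @ (P[:, k] @ Y)
    beta = np.empty_like(params.beta)
    for k in range(K):
        Ak = A[k] + config.ridge * np.eye(p)
        try:
            beta[k] = np.linalg.solve(Ak, b[k])
        except np.linalg.LinAlgError:
            beta[k] = params.beta[k]
    return beta


def m_step(posterior: np.ndarray, data: SufficientSummaries | TrajectoryDataset,
           structure: ModelStructure, prev_params: MixtureParams | None = None,
           config: FitConfig | None = None) -> MixtureParams:
    """One M-step: update pi (closed form), beta (GLS), then covariances.

    Without ``prev_params`` the update starts from a moment-based guess, so
    the call maximises the expected objective from scratch (e.g. a one-hot
    posterior under structure A yields per-class OLS fits with the pooled
    residual variance).
    """
    config = config or FitConfig(n_starts=1)
    design = _as_design(data, structure)
    posterior = np.asarray(posterior, dtype=float)
    if posterior.shape != (design.n_subjects, structure.n_classes):
        raise ConfigurationError("posterior has wrong shape")
    pi = np.maximum(posterior.mean(axis=0), 1e-10)
    pi = pi / pi.sum()
    if prev_params is None:
        prev_params = _moment_init(design, structure, posterior)
    params = replace(prev_params, pi=pi)
    params = replace(params, beta=_update_beta(params, posterior, design, config))
    params = _update_covariances(params, posterior, design, config)
    return params


def _moment_init(design: SufficientSummaries, structure: ModelStructure,
                 posterior: np.ndarray) -> MixtureParams:
    """Moment-based starting parameters from a (possibly hard) posterior."""
    K = structure.n_classes
    p = structure.fixed_degree + 1
    q = structure.n_random
    beta = np.zeros((K, p))
    sse = 0.0
    nobs = 0
    for k in range(K):
        A = np.zeros((p, p))
        b = np.zeros(p)
        for g in design.pattern_groups:
            X, Y, idx = g["X"], g["Y"], g["idx"]
            w = posterior[idx, k]
            A += w.sum() * X.T @ X
            b += X.T @ (w @ Y)
        beta[k] = np.linalg.solve(A + 1e-8 * np.eye(p), b)
    for g in design.pattern_groups:
        X, Y, idx = g["X"], g["Y"], g["idx"]
        P = posterior[idx]
        for k in range(K):
            R = Y - X @ beta[k]
            sse += float(np.sum(P[:, k][:, None] * R ** 2))
        nobs += Y.size
    var = max(sse / max(nobs, 1), 1e-8)
    pi = np.maximum(posterior.mean(axis=0), 1e-10)
    pi /= pi.sum()
    L = omega = L_by = None
    if q:
        # split total variance between random effects and residual noise;
        # higher-order random effects start smaller (transformed-time scale)
        diag = 0.5 * var * (0.5 ** np.arange(q))
        Lmat = np.diag(np.sqrt(diag))
        sigma2 = np.array([0.5 * var])
        if structure.random_cov_mode == "by_class":
            L_by = np.stack([Lmat.copy() for _ in range(K)])
        else:
            L = Lmat
        if structure.random_cov_mode == "proportional":
            omega = np.ones(K)
    else:
        sigma2 = np.full(K if structure.residual_mode == "by_class" else 1, var)
    return MixtureParams(structure=structure, beta=beta, pi=pi, L=L, omega=omega,
                         L_by_class=L_by, sigma2=sigma2)


# --------------------------------------------------------------------------
# EM driver with multi-start
# --------------------------------------------------------------------------

def _subject_coefficients(design: SufficientSummaries, degree: int) -> np.ndarray:
    """Per-subject OLS polynomial coefficients (padded), for initial clustering."""
    N = design.n_subjects
    out = np.zeros((N, degree + 1))
    for i, s in enumerate(design.subjects):
        d_i = min(degree, s.n_obs - 1)
        Xi = s.X[:, : d_i + 1]
        coef, *_ = np.linalg.lstsq(Xi, s.y, rcond=None)
        out[i, : d_i + 1] = coef
    return out


def _initial_posteriors(design: SufficientSummaries, structure: ModelStructure,
                        config: FitConfig) -> list[np.ndarray]:
    """One hard-assignment posterior per EM start (start 1 = k-means)."""
    K = structure.n_classes
    N = design.n_subjects
    rng = np.random.default_rng(config.seed)
    posts = []
    if K == 1:
        return [np.ones((N, 1)) for _ in range(config.n_starts)]
    coefs = _subject_coefficients(design, structure.fixed_degree)
    sd = coefs.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=K, n_init=5, random_state=config.seed % (2 ** 31))
    base = km.fit_predict(coefs / sd)
    for s in range(config.n_starts):
        labels = base.copy()
        if s > 0:
            flip = rng.random(N) < 0.3
            labels[flip] = rng.integers(0, K, size=int(flip.sum()))
        post = np.zeros((N, K))
        post[np.arange(N), labels] = 1.0
        # guard against empty initial classes
        empty = np.where(post.sum(axis=0) == 0)[0]
        for k in empty:
            post[rng.integers(0, N)] = 0.0
            post[rng.integers(0, N), k] = 1.0
        posts.append(post)
    return posts


@dataclass
class _EMResult:
    params: MixtureParams
    loglik: float
    posterior: np.ndarray
    n_iter: int
    converged: bool
    warnings: list[str]
    loglik_trace: np.ndarray
    flagged: np.ndarray


def _em_once(design: SufficientSummaries, structure: ModelStructure,
             post0: np.ndarray, config: FitConfig) -> _EMResult:
    q = structure.n_random
    warnings_: list[str] = []
    params = m_step(post0, design, structure, prev_params=None, config=config)
    trace = []
    prev_ll = -np.inf
    converged = False
    ll, post, flagged = -np.inf, post0, np.array([], dtype=int)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        ll, post, flagged = _loglik_and_posterior(params, design, ridge=config.ridge)
        trace.append(ll)
        if not np.isfinite(ll):
            warnings_.append("non-finite log-likelihood; start abandoned")
            break
        if abs(ll - prev_ll) <= config.tol * (1.0 + abs(ll)):
            converged = True
            break
        prev_ll = ll
        W = post.sum(axis=0)
        for k in np.where(W < q + 1)[0]:
            warnings_.append(f"class {k} effectively empty (weight {W[k]:.3g})")
        params = m_step(post, design, structure, prev_params=params, config=config)
    small = np.where(params.pi < config.min_class_prop_warn)[0]
    for k in small:
        warnings_.append(f"class {k} below {config.min_class_prop_warn:.1%} of the sample")
    degenerate = bool((post.sum(axis=0) < 1.0).any()) or not np.isfinite(ll)
    return _EMResult(params=params, loglik=ll, posterior=post, n_iter=n_iter,
                     converged=converged and not degenerate,
                     warnings=warnings_, loglik_trace=np.asarray(trace), flagged=flagged)


def fit(data: TrajectoryDataset | SufficientSummaries, structure: ModelStructure,
        config: FitConfig | None = None) -> FittedModel:
    """Best-of-``n_starts`` EM fit; classes returned in descending-``pi`` order.

    Non-convergence (no start reached the tolerance, or the best solution
    is degenerate) is reported through ``FittedModel.converged`` — the
    model is still returned so sweeps can tabulate the failure, mirroring
    how class-enumeration tables mark failed candidates.
    """
    config = config or FitConfig()
    design = _as_design(data, structure)
    q = structure.n_random
    max_obs = max(s.n_obs for s in design.subjects)
    if q and max_obs <= q:
        raise DataError(
            f"structure {structure.structure_code} needs subjects with more than "
            f"{q} observations; maximum seen is {max_obs}")
    results: list[_EMResult] = []
    for post0 in _initial_posteriors(design, structure, config):
        try:
            results.append(_em_once(design, structure, post0, config))
        except NumericalError as exc:
            res = _EMResult(params=None, loglik=-np.inf, posterior=post0, n_iter=0,
                            converged=False, warnings=[str(exc)],
                            loglik_trace=np.array([]), flagged=np.array([], dtype=int))
            results.append(res)
    finite = [r for r in results if np.isfinite(r.loglik)]
    if not finite:
        raise NonConvergenceError(
            "all EM starts failed: " + "; ".join(w for r in results for w in r.warnings))
    best = max(finite, key=lambda r: r.loglik)
    return _to_fitted(best, design, structure, config)


def _to_fitted(res: _EMResult, design: SufficientSummaries, structure: ModelStructure,
               config: FitConfig) -> FittedModel:
    params = res.params
    order = np.argsort(-params.pi, kind="stable")
    K = structure.n_classes
    beta = params.beta[order]
    pi = params.pi[order]
    posterior = res.posterior[:, order]
    omega = None
    B = None
    B_by = None
    sigma2 = params.sigma2.copy()
    if structure.random_cov_mode in ("shared", "proportional"):
        B = params.B
    if structure.random_cov_mode == "proportional":
        # re-impose the identifiability convention omega[last] == 1 after reordering
        omega = params.omega[order]
        scale = omega[-1]
        omega = omega / scale
        B = scale ** 2 * B
    if structure.random_cov_mode == "by_class":
        B_by = params.B_by_class[order]
    if structure.residual_mode == "by_class":
        sigma2 = sigma2[order]
    warnings_ = list(res.warnings)
    if res.flagged.size:
        warnings_.append(f"{res.flagged.size} subject(s) with density underflow")
    return FittedModel(
        structure=structure, beta=beta, pi=pi, B=B, omega=omega, B_by_class=B_by,
        sigma2=sigma2, loglik=res.loglik, n_subjects=design.n_subjects,
        n_params=count_parameters(structure), posterior=posterior,
        assignment=np.argmax(posterior, axis=1), subject_ids=design.subject_ids,
        converged=res.converged, n_iter=res.n_iter, n_starts_used=config.n_starts,
        seed=config.seed, warnings_=warnings_, loglik_trace=res.loglik_trace)


def bic(model: FittedModel) -> float:
    """Bayesian information criterion, ``-2 l + p ln N`` (N = subjects)."""
    if not model.converged:
        raise NonConvergenceError("BIC is undefined for a non-converged model")
    return -2.0 * model.loglik + model.n_params * math.log(model.n_subjects)
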