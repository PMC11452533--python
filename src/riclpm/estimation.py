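"""Full-information maximum likelihood estimation of RI-CLPM specifications.

The likelihood is the casewise multivariate-normal likelihood over each
subject's observed variables (valid under MAR missingness). Subjects are
grouped by missingness pattern; each pattern contributes through its
sufficient statistics (count, mean, scatter), so the cost of one likelihood
evaluation is independent of n.

The gradient is assembled in two stages: the pattern-level gradient with
respect to the implied mean vector and covariance matrix is analytic, and is
contracted with the Jacobian of the moment map theta -> (mu, Sigma). Jacobian
columns for slots that enter the moments linearly with theta-free structure
(means, predictor moments, random-intercept covariances, predictor paths) are
exact; columns that run through the transition recursion (wave-1 covariance,
transition matrices, residual covariances) use central differences on the
moment assembly, which is accurate to ~1e-10 and costs two small matrix
assemblies per parameter.

Optimization is Fisher scoring: Newton-type steps scaled by the expected
information (assembled from the same moment Jacobian as the gradient, so a
step costs little more than a gradient), an Armijo backtracking line search
on the log-likelihood, and projection onto the box constraints that keep
variance slots nonnegative. Non-positive-definite proposals evaluate to -inf
and the line search backtracks away from them; seeded jittered restarts
handle the rare non-converged fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .model import ModelSpec, implied_moments, standardize, _structured

__all__ = [
    "MissingnessPattern",
    "FitOptions",
    "FitResult",
    "missingness_patterns",
    "fiml_loglik",
    "fit",
    "standard_errors",
    "icc",
    "ri_variance_explained",
    "predictor_effects",
    "em_saturated",
]

_BIG = 1e15
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class MissingnessPattern:
    """One missingness pattern with its sufficient statistics."""

    mask: np.ndarray  # bool (p,) — True where observed
    indices: np.ndarray  # int indices of observed columns
    count: int
    mean: np.ndarray  # (p_o,) pattern mean
    scatter: np.ndarray  # (p_o, p_o) sum of (x - mean)(x - mean)'
    rows: np.ndarray  # row positions in the input (for per-subject scores)
    data: np.ndarray  # (count, p_o) observed sub-matrix

    @property
    def label(self) -> str:
        return "".join("1" if m else "0" for m in self.mask)


def _as_matrix(panel, variable_names=None):
    if isinstance(panel, pd.DataFrame):
        if variable_names is not None:
            missing = [v for v in variable_names if v not in panel.columns]
            if missing:
                raise ValueError(f"panel is missing model variables: {missing}")
            return panel[list(variable_names)].to_numpy(dtype=float)
        return panel.to_numpy(dtype=float)
    return np.asarray(panel, dtype=float)


def missingness_patterns(panel, variable_names=None):
    """Partition subjects by missingness mask.

    Returns ``(patterns, n_used, n_dropped)``; subjects observed on zero
    columns are excluded with a warning (they cannot contribute to the
    likelihood). Patterns are ordered deterministically by mask.
    """
    X = _as_matrix(panel, variable_names)
    if X.ndim != 2:
        raise ValueError("panel must be 2-D (subjects x variables)")
    obs = ~np.isnan(X)
    any_obs = obs.any(axis=1)
    n_dropped = int((~any_obs).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} subject(s) with no observed model variables", stacklevel=2
        )
    X = X[any_obs]
    obs = obs[any_obs]
    row_pos = np.flatnonzero(any_obs)

    patterns = []
    masks, inverse = np.unique(obs, axis=0, return_inverse=True)
    order = np.lexsort(masks.T[::-1])
    for mi in order:
        mask = masks[mi]
        rows = np.flatnonzero(inverse == mi)
        idx = np.flatnonzero(mask)
        sub = X[np.ix_(rows, idx)]
        mean = sub.mean(axis=0)
        centered = sub - mean
        patterns.append(
            MissingnessPattern(
                mask=mask,
                indices=idx,
                count=len(rows),
                mean=mean,
                scatter=centered.T @ centered,
                rows=row_pos[rows],
                data=sub,
            )
        )
    return patterns, int(any_obs.sum()), n_dropped


# ----------------------------------------------------------------------
# likelihood and gradients
# ----------------------------------------------------------------------


def _pattern_loglik(mu, Sigma, patterns, strict=False):
    """FIML log-likelihood from pattern sufficient statistics.

    Returns -inf on a non-positive-definite sub-block unless ``strict``, in
    which case the offending pattern is named.
    """
    ll = 0.0
    for pat in patterns:
        idx = pat.indices
        S = Sigma[np.ix_(idx, idx)]
        try:
            c, low = cho_factor(S, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            if strict:
                raise np.linalg.LinAlgError(
                    f"singular implied covariance sub-block for pattern {pat.label}"
                ) from None
            return -np.inf
        logdet = 2.0 * np.log(np.diag(c)).sum()
        d = pat.mean - mu[idx]
        Sinv_scatter = cho_solve((c, low), pat.scatter, check_finite=False)
        quad = d @ cho_solve((c, low), d, check_finite=False)
        p_o = len(idx)
        ll -= 0.5 * (
            pat.count * (p_o * _LOG2PI + logdet + quad) + np.trace(Sinv_scatter)
        )
    return ll


def _pattern_loglik_and_moment_grad(mu, Sigma, patterns):
    """Log-likelihood plus its gradient w.r.t. (mu, Sigma).

    The Sigma gradient is returned as the full symmetric matrix W such that
    d ll = sum(W * dSigma) for symmetric perturbations.
    """
    p = len(mu)
    ll = 0.0
    Gmu = np.zeros(p)
    GSig = np.zeros((p, p))
    for pat in patterns:
        idx = pat.indices
        S = Sigma[np.ix_(idx, idx)]
        try:
            c, low = cho_factor(S, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return -np.inf, Gmu, GSig
        logdet = 2.0 * np.log(np.diag(c)).sum()
        d = pat.mean - mu[idx]
        Sinv = cho_solve((c, low), np.eye(len(idx)), check_finite=False)
        Sinv_d = Sinv @ d
        Sinv_scatter_Sinv = Sinv @ pat.scatter @ Sinv
        p_o = len(idx)
        ll -= 0.5 * (
            pat.count * (p_o * _LOG2PI + logdet + d @ Sinv_d)
            + np.trace(Sinv @ pat.scatter)
        )
        Gmu[idx] += pat.count * Sinv_d
        W = 0.5 * (
            Sinv_scatter_Sinv + pat.count * (np.outer(Sinv_d, Sinv_d) - Sinv)
        )
        GSig[np.ix_(idx, idx)] += W
    return ll, Gmu, GSig


def fiml_loglik(spec: ModelSpec, theta, patterns) -> float:
    """FIML log-likelihood of the model at theta over missingness patterns."""
    mu, Sigma = implied_moments(spec, theta)
    ll = _pattern_loglik(mu, Sigma, patterns, strict=True)
    return float(ll)


def _moment_jacobian(spec: ModelSpec, theta, h: float = 1e-6):
    """Jacobian of the moment map: (q, p) mean part and (q, p, p) covariance part.

    Analytic columns for linear slots; central differences through the
    transition recursion otherwise.
    """
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    q = spec.n_free
    p = spec.n_observed
    p_x = K * T
    dmu = np.zeros((q, p))
    dSig = np.zeros((q, p, p))
    slots = spec.params["slot"].to_numpy()

    # means: mu position k*T + t
    for k in range(K):
        for t in range(T):
            dmu[spec.mean_idx[k, t], k * T + t] = 1.0

    fd_params = []
    if cfg.predictor != "none":
        _, _, _, _, _, _, var_g, b = _structured(spec, theta)
        dmu[spec.mug_idx, p_x] = 1.0
        if cfg.predictor == "on_random_intercepts":
            # var_g: bb' on x-block, b on the g row/col, 1 at (g, g)
            bx = np.repeat(b, T)
            D = dSig[spec.varg_idx]
            # Omega gains outer(b, b), replicated over every wave pair
            for k in range(K):
                for l in range(K):
                    D[k * T : (k + 1) * T, l * T : (l + 1) * T] = b[k] * b[l]
            D[p_x, :p_x] = bx
            D[:p_x, p_x] = bx
            D[p_x, p_x] = 1.0
            for k in range(K):
                Dk = dSig[spec.b_idx[k]]
                for l in range(K):
                    add = var_g * b[l]
                    Dk[k * T : (k + 1) * T, l * T : (l + 1) * T] += add
                    Dk[l * T : (l + 1) * T, k * T : (k + 1) * T] += add
                Dk[p_x, k * T : (k + 1) * T] = var_g
                Dk[k * T : (k + 1) * T, p_x] = var_g
        else:
            # on_observed paths run through outer(c, c); finite-difference them
            fd_params.extend(np.unique(spec.b_idx).tolist())
            fd_params.append(spec.varg_idx)

    # random-intercept covariances: constant indicator over wave pairs
    done = set()
    for k in range(K):
        for l in range(K):
            j = spec.psi_idx[k, l]
            if j in done:
                continue
            done.add(j)
            D = dSig[j]
            D[k * T : (k + 1) * T, l * T : (l + 1) * T] = 1.0
            if l != k:
                D[l * T : (l + 1) * T, k * T : (k + 1) * T] = 1.0

    # slots through the within-process recursion: central finite differences
    fd_params.extend(
        np.flatnonzero(np.isin(slots, ("wave1_cov", "transition", "residual_cov"))).tolist()
    )
    theta = np.asarray(theta, dtype=float)
    for j in sorted(set(fd_params)):
        hj = h * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += hj
        mu_p, Sig_p = implied_moments(spec, tp)
        tp[j] -= 2 * hj
        mu_m, Sig_m = implied_moments(spec, tp)
        dmu[j] = (mu_p - mu_m) / (2 * hj)
        dSig[j] = (Sig_p - Sig_m) / (2 * hj)
    return dmu, dSig


def _nll_and_grad(spec, theta, patterns):
    mu, Sigma = implied_moments(spec, theta)
    ll, Gmu, GSig = _pattern_loglik_and_moment_grad(mu, Sigma, patterns)
    if not np.isfinite(ll):
        return _BIG, np.zeros(spec.n_free)
    dmu, dSig = _moment_jacobian(spec, theta)
    grad = dmu @ Gmu + np.einsum("qab,ab->q", dSig, GSig)
    return -ll, -grad


def _expected_information(Sigma, patterns, dmu, dSig):
    """Expected (Fisher) information of theta under the implied moments.

    I_jk = sum over patterns n * [dmu_j' S^-1 dmu_k + 1/2 tr(S^-1 dSig_j
    S^-1 dSig_k)] on the observed sub-blocks. Positive semidefinite by
    construction, which makes it a robust Newton-type scaling matrix.
    """
    q = dmu.shape[0]
    info = np.zeros((q, q))
    for pat in patterns:
        idx = pat.indices
        Sinv = np.linalg.inv(Sigma[np.ix_(idx, idx)])
        dmu_o = dmu[:, idx]
        dSig_o = dSig[:, idx[:, None], idx[None, :]]
        M = np.einsum("ab,qbc->qac", Sinv, dSig_o)
        info += pat.count * (
            dmu_o @ Sinv @ dmu_o.T + 0.5 * np.einsum("qab,rba->qr", M, M)
        )
    return info


def _fisher_scoring(spec, theta0, patterns, tol, max_iter):
    """Maximize the FIML log-likelihood by Fisher scoring with backtracking.

    The expected information (nearly the Hessian at the optimum) gives
    Newton-quality steps at gradient cost; box constraints on variance slots
    are handled by projection with active-set gradient screening.
    """
    lower = spec.lower_bounds()
    theta = np.clip(theta0, lower, None)
    ll = _pattern_loglik(*implied_moments(spec, theta), patterns)
    if not np.isfinite(ll):
        return theta, -np.inf, 0, np.inf, False
    ridge0 = None
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu, Sigma = implied_moments(spec, theta)
        ll, Gmu, GSig = _pattern_loglik_and_moment_grad(mu, Sigma, patterns)
        dmu, dSig = _moment_jacobian(spec, theta)
        grad = dmu @ Gmu + np.einsum("qab,ab->q", dSig, GSig)

        at_lower = np.isfinite(lower) & (theta <= lower + 1e-12)
        proj = grad.copy()
        proj[at_lower & (proj < 0)] = 0.0
        pnorm = float(np.abs(proj).max())
        if pnorm <= tol * (1.0 + abs(ll)):
            return theta, ll, n_iter, pnorm, True

        info = _expected_information(Sigma, patterns, dmu, dSig)
        if ridge0 is None:
            ridge0 = 1e-10 * max(np.trace(info) / len(theta), 1.0)
        # Newton system restricted to coordinates free to move (a variance at
        # its bound with an outward-pushing gradient stays put)
        active = at_lower & (grad < 0)
        free = ~active
        ridge = ridge0
        step = None
        for _ in range(8):
            try:
                sub = info[np.ix_(free, free)] + ridge * np.eye(int(free.sum()))
                c = np.linalg.cholesky(sub)
                step = np.zeros_like(theta)
                step[free] = np.linalg.solve(c.T, np.linalg.solve(c, grad[free]))
                break
            except np.linalg.LinAlgError:
                ridge *= 100.0
        if step is None:
            return theta, ll, n_iter, pnorm, False

        # backtracking line search on the log-likelihood (ascent)
        slope = grad @ step
        alpha = 1.0
        improved = False
        for _ in range(40):
            cand = np.clip(theta + alpha * step, lower, None)
            ll_new = _pattern_loglik(*implied_moments(spec, cand), patterns)
            if np.isfinite(ll_new) and ll_new >= ll + 1e-4 * alpha * slope - 1e-10 * (1 + abs(ll)):
                theta = cand
                improved = True
                break
            alpha *= 0.5
        if not improved:
            # steepest-ascent fallback scaled by the information diagonal
            d = np.maximum(np.diag(info), 1e-12)
            alpha = 1.0
            for _ in range(40):
                cand = np.clip(theta + alpha * grad / d, lower, None)
                ll_new = _pattern_loglik(*implied_moments(spec, cand), patterns)
                if np.isfinite(ll_new) and ll_new > ll:
                    theta = cand
                    improved = True
                    break
                alpha *= 0.5
            if not improved:
                return theta, ll, n_iter, pnorm, False
    return theta, ll, n_iter, pnorm, False


# ----------------------------------------------------------------------
# saturated EM (used for starting values and, by model_compare, for chi2)
# ----------------------------------------------------------------------


def em_saturated(patterns, p, tol: float = 1e-7, max_iter: int = 2000):
    """ML estimate of an unstructured MVN mean and covariance under missingness.

    Classic EM over missingness patterns; returns ``(mu, Sigma, loglik,
    n_iter)``. With complete data it converges in one step to the sample mean
    and the divide-by-N covariance.
    """
    n = sum(pat.count for pat in patterns)
    mu = np.zeros(p)
    var = np.full(p, np.nan)
    cnt = np.zeros(p)
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    for pat in patterns:
        idx = pat.indices
        cnt[idx] += pat.count
        s1[idx] += pat.count * pat.mean
        s2[idx] += np.diag(pat.scatter) + pat.count * pat.mean**2
    ok = cnt > 0
    mu[ok] = s1[ok] / cnt[ok]
    var[ok] = s2[ok] / cnt[ok] - mu[ok] ** 2
    var[~ok | (var <= 0)] = 1.0
    Sigma = np.diag(var)

    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pat in patterns:
            o = pat.indices
            m = np.flatnonzero(~pat.mask)
            n_pat = pat.count
            d = pat.mean - mu[o]
            scat_o = pat.scatter + n_pat * np.outer(d, d)  # raw scatter about mu_o
            sum_x[o] += n_pat * pat.mean
            sum_xx[np.ix_(o, o)] += pat.scatter + n_pat * np.outer(pat.mean, pat.mean)
            if m.size:
                Soo = Sigma[np.ix_(o, o)]
                c, low = cho_factor(Soo, lower=True, check_finite=False)
                A = cho_solve((c, low), Sigma[np.ix_(o, m)], check_finite=False).T  # (m, o)
                mu_m = mu[m]
                Em_sum = n_pat * mu_m + A @ (n_pat * d)
                sum_x[m] += Em_sum
                # E[x_m x_o'] summed
                cross = (
                    n_pat * np.outer(mu_m, pat.mean)
                    + A @ (pat.scatter + n_pat * np.outer(d, pat.mean))
                )
                sum_xx[np.ix_(m, o)] += cross
                sum_xx[np.ix_(o, m)] += cross.T
                C_mm = Sigma[np.ix_(m, m)] - A @ Sigma[np.ix_(o, m)]
                EmEm = (
                    n_pat * np.outer(mu_m, mu_m)
                    + np.outer(mu_m, A @ (n_pat * d))
                    + np.outer(A @ (n_pat * d), mu_m)
                    + A @ scat_o @ A.T
                )
                sum_xx[np.ix_(m, m)] += n_pat * C_mm + EmEm
        mu = sum_x / n
        Sigma = sum_xx / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _pattern_loglik(mu, Sigma, patterns)
        if not np.isfinite(ll):
            Sigma += 1e-8 * np.trace(Sigma) / p * np.eye(p)
            ll = _pattern_loglik(mu, Sigma, patterns)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            return mu, Sigma, float(ll), it
        ll_old = ll
    return mu, Sigma, float(ll), max_iter


# ----------------------------------------------------------------------
# starting values
# ----------------------------------------------------------------------


def _clip_psd(C, floor_frac=1e-6):
    """Project a symmetric matrix to PSD by flooring eigenvalues."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    floor = max(floor_frac * max(w.max(), 1e-12), 1e-10)
    w = np.clip(w, floor, None)
    return (V * w) @ V.T


def _moment_start(spec: ModelSpec, patterns):
    """Method-of-moments start from a quick saturated EM estimate."""
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    p = spec.n_observed
    p_x = K * T
    mu_hat, Sig_hat, _, _ = em_saturated(patterns, p, tol=1e-5, max_iter=200)

    theta = spec.start_vector()
    for k in range(K):
        for t in range(T):
            theta[spec.mean_idx[k, t]] = mu_hat[k * T + t]
    if cfg.means == "equal_over_waves":
        for k in range(K):
            theta[spec.mean_idx[k, 0]] = mu_hat[k * T : (k + 1) * T].mean()

    # between-person covariance from distant-lag cross-wave covariances
    Omega = np.empty((K, K))
    for k in range(K):
        for l in range(K):
            vals = [
                Sig_hat[k * T + t, l * T + s]
                for t in range(T)
                for s in range(T)
                if t != s
            ]
            Omega[k, l] = np.mean(vals)
    Omega = 0.5 * (Omega + Omega.T)

    if cfg.predictor == "on_random_intercepts":
        theta[spec.mug_idx] = mu_hat[p_x]
        var_g = max(Sig_hat[p_x, p_x], 1e-8)
        theta[spec.varg_idx] = var_g
        b0 = np.array([Sig_hat[p_x, k * T : (k + 1) * T].mean() / var_g for k in range(K)])
        for k in range(K):
            theta[spec.b_idx[k]] = b0[k]
        Psi0 = _clip_psd(Omega - var_g * np.outer(b0, b0))
    elif cfg.predictor == "on_observed":
        theta[spec.mug_idx] = mu_hat[p_x]
        var_g = max(Sig_hat[p_x, p_x], 1e-8)
        theta[spec.varg_idx] = var_g
        for k in range(K):
            for t in range(T):
                theta[spec.b_idx[k, t]] = Sig_hat[p_x, k * T + t] / var_g
        Psi0 = _clip_psd(Omega)
    else:
        Psi0 = _clip_psd(Omega)

    for k in range(K):
        for l in range(k, K):
            theta[spec.psi_idx[k, l]] = Psi0[k, l]

    # within-process wave covariances and transitions
    C = []
    for t in range(T):
        idx = np.array([k * T + t for k in range(K)])
        C.append(_clip_psd(Sig_hat[np.ix_(idx, idx)] - Omega))
    for k in range(K):
        for l in range(k, K):
            theta[spec.sw1_idx[k, l]] = C[0][k, l]

    B0 = []
    for t in range(1, T):
        idx_t = np.array([k * T + t for k in range(K)])
        idx_s = np.array([k * T + t - 1 for k in range(K)])
        lag = Sig_hat[np.ix_(idx_t, idx_s)] - Omega
        Bt = lag @ np.linalg.pinv(C[t - 1])
        B0.append(np.clip(Bt, -0.9, 0.9))
    # honor equality groups by averaging tied transitions
    for jidx in np.unique(spec.B_idx):
        pos = np.argwhere(spec.B_idx == jidx)
        theta[jidx] = float(np.mean([B0[t][i, j] for t, i, j in pos]))
    for t in range(1, T):
        Bt = np.array([[theta[spec.B_idx[t - 1, i, j]] for j in range(K)] for i in range(K)])
        Th = _clip_psd(C[t] - Bt @ C[t - 1] @ Bt.T)
        for k in range(K):
            for l in range(k, K):
                theta[spec.theta_idx[t - 1, k, l]] = Th[k, l]

    lower = spec.lower_bounds()
    theta = np.maximum(theta, lower + 0.0)
    return theta


def _default_start(spec: ModelSpec, patterns):
    """Fallback start: available-case means, half pooled variance per component."""
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    p = spec.n_observed
    cnt = np.zeros(p)
    s1 = np.zeros(p)
    s2 = np.zeros(p)
    for pat in patterns:
        idx = pat.indices
        cnt[idx] += pat.count
        s1[idx] += pat.count * pat.mean
        s2[idx] += np.diag(pat.scatter) + pat.count * pat.mean**2
    mean = np.where(cnt > 0, s1 / np.maximum(cnt, 1), 0.0)
    var = np.where(cnt > 1, s2 / np.maximum(cnt, 1) - mean**2, 1.0)
    var = np.maximum(var, 1e-6)

    theta = spec.start_vector()
    for k in range(K):
        vk = var[k * T : (k + 1) * T].mean()
        for t in range(T):
            theta[spec.mean_idx[k, t]] = mean[k * T + t]
        theta[spec.psi_idx[k, k]] = 0.5 * vk
        theta[spec.sw1_idx[k, k]] = 0.5 * vk
        for t in range(T - 1):
            theta[spec.theta_idx[t, k, k]] = 0.45 * vk
    if cfg.predictor != "none":
        theta[spec.mug_idx] = mean[K * T]
        theta[spec.varg_idx] = max(var[K * T], 1e-6)
        theta[np.asarray(spec.b_idx).ravel()] = 0.0
    return theta


# ----------------------------------------------------------------------
# fit
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    tolerance: float = 1e-6
    max_iter: int = 1000
    start_strategy: str = "auto"  # auto | default | explicit vector via `start`
    seed: int = 0
    restarts: int = 2
    compute_se: bool = True
    se_method: str = "observed_information"


@dataclass
class FitResult:
    """A converged (or explicitly failed) FIML fit with derived quantities."""

    spec: ModelSpec
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_used: int
    n_dropped: int
    options: FitOptions
    se: np.ndarray | None = None
    pattern_census: list = field(default_factory=list)
    boundary: np.ndarray | None = None
    message: str = ""
    _patterns: list = field(default_factory=list, repr=False)

    @property
    def labels(self):
        return list(self.spec.params["label"])

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    def parameter_table(self, significance: float = 0.01) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "label": self.labels,
                "slot": self.spec.params["slot"],
                "estimate": self.theta,
            }
        )
        if self.se is not None:
            tab["se"] = self.se
            with np.errstate(divide="ignore", invalid="ignore"):
                tab["z"] = self.theta / self.se
            tab["p"] = 2 * stats.norm.sf(np.abs(tab["z"]))
            tab["significant"] = tab["p"] < significance
        return tab

    @property
    def standardized(self) -> dict:
        return standardize(self.spec, self.theta)

    def implied_moments(self):
        return implied_moments(self.spec, self.theta)

    def to_dict(self, significance: float = 0.01) -> dict:
        tab = self.parameter_table(significance)
        std = self.standardized
        out = {
            "config": {
                "n_constructs": self.spec.config.n_constructs,
                "n_waves": self.spec.config.n_waves,
                "scheme": self.spec.config.scheme,
                "means": self.spec.config.means,
                "predictor": self.spec.config.predictor,
                "construct_labels": list(self.spec.config.construct_labels),
            },
            "loglik": self.loglik,
            "n_free_parameters": self.n_free,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "convergence": {
                "converged": self.converged,
                "n_iter": self.n_iter,
                "grad_norm": self.grad_norm,
                "message": self.message,
            },
            "parameters": tab.replace({np.nan: None}).to_dict(orient="records"),
            "standardized": {k: np.asarray(v).tolist() for k, v in std.items()},
            "derived": {
                "icc": icc(self).tolist(),
                "ri_variance_explained": ri_variance_explained(self).tolist(),
            },
            "missingness_patterns": [
                {"mask": lbl, "count": cnt} for lbl, cnt in self.pattern_census
            ],
        }
        if self.spec.config.predictor == "on_random_intercepts":
            eff = predictor_effects(self)
            out["derived"]["predictor_beta_std"] = eff["beta_std"].tolist()
            out["derived"]["predictor_variance_share"] = eff["variance_share"].tolist()
        return out


class FitFailure(RuntimeError):
    """Raised when optimization does not converge within the restart budget."""

    def __init__(self, message, diagnostics):
        super().__init__(message)
        self.diagnostics = diagnostics


def fit(spec: ModelSpec, panel, options: FitOptions | None = None, start=None) -> FitResult:
    """Fit the model to a panel by FIML.

    ``panel`` may be a DataFrame carrying the spec's variable names or a plain
    matrix in spec column order. Raises :class:`FitFailure` if no restart
    converges; never returns a silently non-converged result.
    """
    options = options or FitOptions()
    patterns, n_used, n_dropped = missingness_patterns(panel, spec.variable_names)
    if n_used <= spec.n_free:
        warnings.warn(
            f"n ({n_used}) not larger than the number of free parameters ({spec.n_free})",
            stacklevel=2,
        )

    if start is not None:
        theta0 = np.asarray(start, dtype=float).copy()
    elif options.start_strategy == "default":
        theta0 = _default_start(spec, patterns)
    else:
        try:
            theta0 = _moment_start(spec, patterns)
        except Exception:
            theta0 = _default_start(spec, patterns)
    lower = spec.lower_bounds()
    theta0 = np.maximum(theta0, lower)
    nll0, _ = _nll_and_grad(spec, theta0, patterns)
    if nll0 >= _BIG:
        theta0 = _default_start(spec, patterns)
        nll0, _ = _nll_and_grad(spec, theta0, patterns)

    rng = np.random.default_rng(options.seed)
    attempts = []
    theta_try = theta0
    for attempt in range(options.restarts + 1):
        theta_hat, ll, n_iter, pnorm, converged = _fisher_scoring(
            spec, theta_try, patterns, options.tolerance, options.max_iter
        )
        attempts.append({"loglik": ll, "grad_norm": pnorm, "nit": n_iter})
        if converged:
            at_lower = np.isfinite(lower) & (theta_hat <= lower + 1e-12)
            boundary = at_lower & (spec.params["slot"].isin(
                ("ri_cov", "wave1_cov", "residual_cov", "predictor_var")
            ).to_numpy())
            if boundary.any():
                warnings.warn(
                    "variance parameter(s) at the boundary: "
                    + ", ".join(spec.params["label"][boundary]),
                    stacklevel=2,
                )
            result = FitResult(
                spec=spec,
                theta=theta_hat.copy(),
                loglik=float(ll),
                converged=True,
                n_iter=int(n_iter),
                grad_norm=pnorm,
                n_used=n_used,
                n_dropped=n_dropped,
                options=options,
                pattern_census=[(pat.label, pat.count) for pat in patterns],
                boundary=boundary,
                message="converged (Fisher scoring)",
                _patterns=patterns,
            )
            if options.compute_se:
                result.se = standard_errors(result, method=options.se_method)
            return result
        # jittered restart from the best point so far
        scale = 0.05 * (1.0 + np.abs(theta_hat))
        theta_try = np.maximum(theta_hat + rng.normal(0.0, scale), lower)
    raise FitFailure(
        f"optimization failed to converge after {options.restarts + 1} attempt(s)",
        diagnostics=attempts,
    )


# ----------------------------------------------------------------------
# standard errors
# ----------------------------------------------------------------------


def _observed_information(fitres: FitResult, h: float = 1e-4):
    """Negative Hessian of the FIML log-likelihood by central differences on
    the (semi-analytic) gradient."""
    spec, theta, patterns = fitres.spec, fitres.theta, fitres._patterns
    q = spec.n_free
    H = np.empty((q, q))
    for j in range(q):
        hj = h * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += hj
        _, gp = _nll_and_grad(spec, tp, patterns)
        tp[j] -= 2 * hj
        _, gm = _nll_and_grad(spec, tp, patterns)
        H[j] = (gp - gm) / (2 * hj)  # gradient of nll -> +Hessian of nll
    return 0.5 * (H + H.T)


def _score_matrix(fitres: FitResult):
    """Per-subject score vectors at theta-hat (n_used x q)."""
    spec, theta, patterns = fitres.spec, fitres.theta, fitres._patterns
    mu, Sigma = implied_moments(spec, theta)
    dmu, dSig = _moment_jacobian(spec, theta)
    scores = np.empty((fitres.n_used, spec.n_free))
    row = 0
    for pat in patterns:
        idx = pat.indices
        Sinv = np.linalg.inv(Sigma[np.ix_(idx, idx)])
        Z = (pat.data - mu[idx]) @ Sinv  # (n_pat, p_o)
        dmu_o = dmu[:, idx]  # (q, p_o)
        dSig_o = dSig[:, idx[:, None], idx[None, :]]  # (q, p_o, p_o)
        tr_term = np.einsum("ab,qab->q", Sinv, dSig_o)
        quad = np.einsum("na,qab,nb->nq", Z, dSig_o, Z)
        s = Z @ dmu_o.T + 0.5 * (quad - tr_term[None, :])
        scores[row : row + pat.count] = s
        row += pat.count
    return scores


def standard_errors(fitres: FitResult, method: str = "observed_information") -> np.ndarray:
    """Standard errors at the optimum.

    ``observed_information``: sqrt of the diagonal of the inverse negative
    Hessian. ``sandwich``: A^-1 B A^-1 with A the negative Hessian and B the
    sum of per-subject score outer products (robust to non-normality).
    """
    A = _observed_information(fitres)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("model not locally identified (singular Hessian)") from None
    if method == "observed_information":
        V = Ainv
    elif method == "sandwich":
        S = _score_matrix(fitres)
        B = S.T @ S
        V = Ainv @ B @ Ainv
    else:
        raise ValueError("method must be 'observed_information' or 'sandwich'")
    d = np.diag(V).copy()
    bad = d <= 0
    if bad.any():
        warnings.warn(
            "non-positive variance estimate for parameter(s): "
            + ", ".join(np.asarray(fitres.labels)[bad]),
            stacklevel=2,
        )
        d[bad] = np.nan
    return np.sqrt(d)


# ----------------------------------------------------------------------
# derived quantities
# ----------------------------------------------------------------------


def _between_and_total(fitres: FitResult):
    spec, theta = fitres.spec, fitres.theta
    cfg = spec.config
    K, T = cfg.n_constructs, cfg.n_waves
    _, Psi, _, _, _, _, var_g, b = _structured(spec, theta)
    if cfg.predictor == "on_random_intercepts":
        Omega = Psi + var_g * np.outer(b, b)
    else:
        Omega = Psi
    _, Sigma = implied_moments(spec, theta)
    total = np.diag(Sigma)[: K * T].reshape(K, T)
    return Omega, total


def icc(fitres: FitResult) -> np.ndarray:
    """Per-construct intra-class correlation.

    Between-person variance (random intercept plus predictor channel) over the
    wave-averaged implied total variance of the construct.
    """
    Omega, total = _between_and_total(fitres)
    return np.diag(Omega) / total.mean(axis=1)


def ri_variance_explained(fitres: FitResult) -> np.ndarray:
    """Share of each indicator's implied variance due to the stable component.

    (K, T) array; equals the squared standardized random-intercept loading.
    """
    Omega, total = _between_and_total(fitres)
    return np.diag(Omega)[:, None] / total


def predictor_effects(fitres: FitResult) -> dict:
    """Standardized effect of the predictor on each random intercept.

    Returns ``beta_std`` (K,) — b_k sigma_g over the total RI SD — and
    ``variance_share`` (K, T) — the share of each indicator's variance the
    predictor explains, equal to beta_std^2 times the RI R-squared.
    """
    spec = fitres.spec
    if spec.config.predictor != "on_random_intercepts":
        raise ValueError("fit has no predictor on the random intercepts")
    _, _, _, _, _, _, var_g, b = _structured(spec, fitres.theta)
    Omega, total = _between_and_total(fitres)
    beta_std = b * np.sqrt(var_g) / np.sqrt(np.diag(Omega))
    share = (b**2 * var_g)[:, None] / total
    return {"beta_std": beta_std, "variance_share": share}
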