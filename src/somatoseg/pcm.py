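"""Pattern component modeling.

Hierarchical random-effects model of condition x voxel activity patterns:

    Y = Z U + E,    U[:, j] ~ N(0, G),    E[i, j] ~ N(0, sigma2) iid,

with Y the n x v data (conditions x voxels), Z the n x p design, U the p x v
pattern components and G the p x p pattern covariance. Marginally each voxel
column is N(0, V) with V = Z G Z' + sigma2 I, so only the sample second
moment S = Y Y' / v enters the likelihood. G and sigma2 are estimated by
Expectation-Maximization over the latent U; a generic numerical maximizer of
the same marginal likelihood (Cholesky parameterization) serves as an
independent validation oracle.

Representational similarity between conditions is read off the normalized G
(see :mod:`somatoseg.similarity`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import FactorialIndex, ValidationError


@dataclass
class BetaMatrix:
    """Conditions x voxels regression-coefficient matrix for one ROI."""

    Y: np.ndarray
    cell_labels: list | None = None
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValidationError("Y must be 2D (conditions x voxels)")
        if self.Y.shape[1] and np.isnan(self.Y).all(axis=0).all():
            raise ValidationError("all columns of Y are NaN")
        if self.Y.shape[1] < self.Y.shape[0]:
            warnings.warn(
                f"fewer voxels ({self.Y.shape[1]}) than conditions ({self.Y.shape[0]})",
                stacklevel=2)


@dataclass
class PCMFit:
    G_hat: np.ndarray
    sigma2_hat: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    roi_name: str = ""

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _as_matrix(Y) -> np.ndarray:
    Y = Y.Y if isinstance(Y, BetaMatrix) else np.asarray(Y, dtype=float)
    # masked voxels are dropped column-wise
    keep = ~np.isnan(Y).any(axis=0)
    return Y[:, keep]


def marginal_loglik(Y, Z: np.ndarray, G: np.ndarray, sigma2: float) -> float:
    """Marginal log-likelihood sum_j log N(y_j; 0, V), V = Z G Z' + sigma2 I.

    Equals ``-(v/2) * (n log 2pi + log|V| + tr(V^-1 S))`` with S = Y Y' / v.
    """
    Y = _as_matrix(Y)
    Z = np.asarray(Z, dtype=float)
    n, v = Y.shape
    if Z.shape[0] != n:
        raise ValidationError(f"Z has {Z.shape[0]} rows, Y has {n}")
    V = Z @ np.asarray(G, dtype=float) @ Z.T + float(sigma2) * np.eye(n)
    w = np.linalg.eigvalsh(V)
    if w.min() <= 0:
        raise ValidationError(f"V singular: min eigenvalue {w.min():.3e}")
    S = (Y @ Y.T) / v
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * v * (n * np.log(2 * np.pi) + logdet + np.trace(np.linalg.solve(V, S)))


def _default_init(S: np.ndarray, Z: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
    """G0 = diag of the second moment of the projected patterns; sigma20 from
    half the residual variance after projecting Y onto col(Z) (floored)."""
    n, v = Y.shape
    Zp = np.linalg.pinv(Z)
    Up = Zp @ Y
    G0 = np.diag(np.maximum(np.diag(Up @ Up.T / v), 1e-8 * max(np.trace(S) / n, 1.0)))
    resid = Y - Z @ Up
    s20 = 0.5 * float((resid**2).mean()) if resid.size else 0.0
    s20 = max(s20, 1e-3 * np.trace(S) / n, 1e-10)
    return G0, s20


def fit_pcm_em(Y, Z: np.ndarray, init: tuple[np.ndarray, float] | None = None,
               tol: float = 1e-6, max_iter: int = 1000,
               fix_sigma2: float | None = None, roi_name: str = "",
               expand: bool = True) -> PCMFit:
    """Maximum-likelihood (G, sigma2) by EM over the latent patterns U.

    E-step: posterior of each u_j given y_j under the current (G, sigma2),
    expressed without inverting G: with W = V^-1 and B = G Z' W,
    E[u_j] = B y_j and Cov[u_j] = G - G Z' W Z G.
    M-step: G <- average posterior second moment of U over voxels,
    sigma2 <- average posterior residual second moment.

    With ``expand=True`` the M-step uses the parameter-expanded (PX-EM)
    update: the model is embedded in Y = Z A U* + E with an auxiliary mixing
    matrix A estimated by least squares and folded back into G = A G* A'.
    PX-EM preserves the monotone ascent of the marginal likelihood while
    removing the slow crawl plain EM shows near variance boundaries.

    ``fix_sigma2`` pins the noise variance (e.g. 0 with invertible Z G Z',
    in which case the ML G satisfies Z G Z' = S). The returned G is projected
    onto the PSD cone at exit only.
    """
    roi = roi_name or (Y.roi_name if isinstance(Y, BetaMatrix) else "")
    Ym = _as_matrix(Y)
    Z = np.asarray(Z, dtype=float)
    n, v = Ym.shape
    if v < 2:
        raise ValidationError("need at least 2 voxels")
    p = Z.shape[1]
    S = (Ym @ Ym.T) / v

    if init is not None:
        G = np.asarray(init[0], dtype=float).copy()
        s2 = float(init[1])
    else:
        G, s2 = _default_init(S, Z, Ym)
    if fix_sigma2 is not None:
        s2 = float(fix_sigma2)

    eye_n = np.eye(n)
    trace_ll = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = Z @ G @ Z.T + s2 * eye_n
        w = np.linalg.eigvalsh(V)
        if w.min() <= 0:
            raise ValidationError(f"V singular at iteration {it}: min eig {w.min():.3e}")
        sign, logdet = np.linalg.slogdet(V)
        Winv_S = np.linalg.solve(V, S)
        ll = -0.5 * v * (n * np.log(2 * np.pi) + logdet + np.trace(Winv_S))
        if not np.isfinite(ll):
            raise ValidationError("non-finite marginal log-likelihood")
        trace_ll.append(ll)
        if len(trace_ll) > 1:
            prev = trace_ll[-2]
            if abs(ll - prev) < tol * (1.0 + abs(ll)):
                converged = True
                break

        ZtW = np.linalg.solve(V, Z).T          # p x n  == Z' V^-1
        B = G @ ZtW                            # p x n
        Sigma_u = G - B @ Z @ G                # posterior covariance of u_j
        M2 = B @ S @ B.T                       # average posterior mean outer product
        Euu = 0.5 * (M2 + Sigma_u + (M2 + Sigma_u).T)
        w_euu = np.linalg.eigvalsh(Euu)
        if expand and w_euu.min() > 1e-12 * max(w_euu.max(), 1e-300):
            # PX M-step: A = argmin E||Y - Z A U||^2, G <- A E[uu'] A'
            Syu = S @ B.T                      # n x p, average E[y u']
            rhs = Z.T @ Syu
            A = np.linalg.solve(Z.T @ Z, np.linalg.solve(Euu.T, rhs.T).T)
            G_new = A @ Euu @ A.T
            ZA = Z @ A
        else:
            G_new = Euu
            ZA = Z
        G_new = 0.5 * (G_new + G_new.T)
        if fix_sigma2 is None:
            # E||y - (Z A) u||^2 averaged over voxels and trials
            Syu_full = S @ B.T
            e2 = (np.trace(S) - 2 * np.trace(ZA.T @ Syu_full)
                  + np.trace(ZA @ Euu @ ZA.T))
            s2 = max(float(e2) / n, 1e-12)
        G = G_new

    if not converged:
        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)

    # PSD repair at exit only
    wG, Q = np.linalg.eigh(0.5 * (G + G.T))
    G = (Q * np.clip(wG, 0.0, None)) @ Q.T
    return PCMFit(G, s2, np.asarray(trace_ll), it, converged, roi)


def _chol_unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, float]:
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = theta[:-1]
    return L @ L.T, float(np.exp(theta[-1]))


def fit_pcm_direct(Y, Z: np.ndarray, roi_name: str = "",
                   maxiter: int = 2000) -> PCMFit:
    """Direct numerical ML over a Cholesky parameterization of G and log
    sigma2 — the independent validation oracle for :func:`fit_pcm_em`.

    Parameter count grows as p(p+1)/2 + 1; intended for small p.
    """
    roi = roi_name or (Y.roi_name if isinstance(Y, BetaMatrix) else "")
    Ym = _as_matrix(Y)
    Z = np.asarray(Z, dtype=float)
    n, v = Ym.shape
    p = Z.shape[1]
    S = (Ym @ Ym.T) / v

    if not np.any(Ym):
        warnings.warn("zero data: G estimate degenerates to the boundary", stacklevel=2)

    G0, s20 = _default_init(S, Z, Ym)
    L0 = np.linalg.cholesky(G0 + 1e-8 * np.eye(p) * max(np.trace(G0), 1.0))
    theta0 = np.concatenate([L0[np.tril_indices(p)], [np.log(s20)]])

    def neg_ll(theta: np.ndarray) -> float:
        G, s2 = _chol_unpack(theta, p)
        V = Z @ G @ Z.T + s2 * np.eye(n)
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2 * np.log(np.diag(c)).sum()
        tr = np.trace(np.linalg.solve(V, S))
        return 0.5 * v * (n * np.log(2 * np.pi) + logdet + tr)

    res = optimize.minimize(neg_ll, theta0, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 10**6,
                                     "ftol": 1e-12, "gtol": 1e-10})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"direct optimizer failed: {res.message}")
    G, s2 = _chol_unpack(res.x, p)
    ll = -res.fun
    return PCMFit(G, s2, np.asarray([ll]), int(res.nit), bool(res.success), roi)


def fit_per_roi(betas: dict[str, "BetaMatrix | np.ndarray"], Z: np.ndarray,
                **kwargs) -> dict[str, PCMFit]:
    """Independent EM fit per ROI; empty ROIs are skipped with a warning."""
    if not betas:
        raise ValidationError("need at least one ROI")
    fits: dict[str, PCMFit] = {}
    for roi, Y in betas.items():
        Ym = Y.Y if isinstance(Y, BetaMatrix) else np.asarray(Y)
        if Ym.size == 0 or Ym.shape[1] == 0:
            warnings.warn(f"ROI {roi!r} empty, skipped", stacklevel=2)
            continue
        fits[roi] = fit_pcm_em(Y, Z, roi_name=roi, **kwargs)
    return fits


def default_design(p: int | None = None) -> np.ndarray:
    """Free-model design: the identity on the 9 factorial cells (no
    constraints on the pattern covariance)."""
    return np.eye(p if p is not None else FactorialIndex().p)
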