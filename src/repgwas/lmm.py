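"""REML fitting of the single-kernel mixed model and BLUP breeding values.

Model: y = X beta + Z g + e with g ~ N(0, K sigma_g^2), e ~ N(0, I sigma_e^2),
so V = Z K Z' sigma_g^2 + I sigma_e^2.  The restricted likelihood is profiled
over the variance ratio delta = sigma_e^2 / sigma_g^2 on the eigenbasis of
Z K Z' projected onto the complement of col(X): one O(N^3) decomposition,
then O(N) per candidate delta.  The search is a dense grid on log delta over
[-10, 10] followed by bounded scalar refinement — deterministic, no random
starts.  Hitting a search bound sets ``boundary`` (heritability pinned near
0 or 1) but is not an error.

Maximum likelihood is available behind ``criterion="ml"`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .design import DesignSystem
from .io_formats import KinshipMatrix

__all__ = ["LmmError", "VarianceComponents", "fit_null", "gls_solve", "estimate_bv"]

LOG_DELTA_BOUNDS = (-10.0, 10.0)
N_GRID = 100


class LmmError(ValueError):
    """Raised when the mixed model cannot be fitted."""


@dataclass
class VarianceComponents:
    """Variance components and fixed effects of the fitted null model."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    beta_hat: np.ndarray
    beta_cov: np.ndarray
    fixed_effect_names: list[str]
    boundary: bool = False
    criterion: str = "reml"

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _eigen_h(Z: np.ndarray, K: np.ndarray):
    h = Z @ K @ Z.T
    d, u = np.linalg.eigh((h + h.T) / 2.0)
    if d[0] < -1e-8 * max(d[-1], 0.0):
        raise LmmError(f"Z K Z' is not positive semidefinite (min eig {d[0]:.3g})")
    return np.clip(d, 0.0, None), u


def _profile_delta(lam: np.ndarray, eta: np.ndarray, q: int):
    """Maximise the profiled restricted likelihood over log delta."""
    eta2 = eta**2

    def negll(logd: float) -> float:
        denom = lam + math.exp(logd)
        ss = float(eta2 @ (1.0 / denom))
        return -0.5 * (
            q * math.log(q / (2.0 * math.pi))
            - q
            - q * math.log(ss)
            - float(np.log(denom).sum())
        )

    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, N_GRID)
    vals = np.array([negll(g) for g in grid])
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, N_GRID - 1)]
    res = minimize_scalar(negll, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-12})
    logd = float(res.x) if res.fun <= vals[i] else float(grid[i])
    boundary = logd <= lo + 1e-6 or logd >= hi - 1e-6
    return math.exp(logd), boundary


def _fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray, Kv: np.ndarray,
         names: list[str], criterion: str = "reml") -> VarianceComponents:
    n_obs, p = X.shape
    if n_obs <= p + 1:
        raise LmmError(f"need N_obs > p + 1 (got N_obs={n_obs}, p={p})")
    d_h, u_h = _eigen_h(Z, Kv)

    if criterion == "reml":
        # orthonormal complement of col(X): eigenvalues of S (ZKZ') S
        qfull, _ = np.linalg.qr(X, mode="complete")
        q2 = qfull[:, p:]
        a = q2.T @ (u_h * d_h) @ (u_h.T @ q2)
        lam, uw = np.linalg.eigh((a + a.T) / 2.0)
        lam = np.clip(lam, 0.0, None)
        eta = uw.T @ (q2.T @ y)
        delta, boundary = _profile_delta(lam, eta, n_obs - p)
        ss = float((eta**2) @ (1.0 / (lam + delta)))
        sigma_g2 = ss / (n_obs - p)
    elif criterion == "ml":
        yt_full = u_h.T @ y
        xt_full = u_h.T @ X

        def negll(logd: float) -> float:
            denom = d_h + math.exp(logd)
            isr = 1.0 / np.sqrt(denom)
            xs = xt_full * isr[:, None]
            ys = yt_full * isr
            beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
            rss = float(((ys - xs @ beta) ** 2).sum())
            return -0.5 * (
                n_obs * math.log(n_obs / (2.0 * math.pi))
                - n_obs
                - n_obs * math.log(rss)
                - float(np.log(denom).sum())
            )

        lo, hi = LOG_DELTA_BOUNDS
        grid = np.linspace(lo, hi, N_GRID)
        vals = np.array([negll(g) for g in grid])
        i = int(np.argmin(vals))
        res = minimize_scalar(
            negll,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, N_GRID - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        logd = float(res.x) if res.fun <= vals[i] else float(grid[i])
        boundary = logd <= lo + 1e-6 or logd >= hi - 1e-6
        delta = math.exp(logd)
        denom = d_h + delta
        isr = 1.0 / np.sqrt(denom)
        xs = (u_h.T @ X) * isr[:, None]
        ys = (u_h.T @ y) * isr
        beta, *_ = np.linalg.lstsq(xs, ys, rcond=None)
        sigma_g2 = float(((ys - xs @ beta) ** 2).sum()) / n_obs
    else:
        raise LmmError(f"unknown criterion {criterion!r}")

    sigma_e2 = delta * sigma_g2
    v_eigvals = sigma_g2 * d_h + sigma_e2
    beta_hat, beta_cov = gls_solve(y, X, u_h, v_eigvals)

    # restricted log-likelihood, normalised with the ln|X'X| offset so the
    # value is invariant to full-rank reparameterizations of X
    r = y - X @ beta_hat
    vinv_r = u_h @ ((u_h.T @ r) / v_eigvals)
    ypy = float(r @ vinv_r)
    logdet_v = float(np.log(v_eigvals).sum())
    xt = (u_h.T @ X) / np.sqrt(v_eigvals)[:, None]
    sign, logdet_xvx = np.linalg.slogdet(xt.T @ xt)
    if sign <= 0:
        raise LmmError("X' V^-1 X is singular")
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    loglik = -0.5 * (
        (n_obs - p) * math.log(2.0 * math.pi)
        + logdet_v
        + logdet_xvx
        - logdet_xx
        + ypy
    )
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        delta=float(delta),
        reml_loglik=float(loglik),
        beta_hat=beta_hat,
        beta_cov=beta_cov,
        fixed_effect_names=list(names),
        boundary=boundary,
        criterion=criterion,
    )


def fit_null(design: DesignSystem, K: KinshipMatrix,
             criterion: str = "reml") -> VarianceComponents:
    """Fit the marker-free mixed model by REML (or ML) variance components."""
    if list(K.line_ids) != list(design.line_ids):
        raise LmmError(
            "kinship matrix is not aligned to the design's lines; "
            "use align_kinship first"
        )
    return _fit(design.y, design.X, design.Z, K.values,
                design.fixed_effect_names, criterion)


def gls_solve(y: np.ndarray, X: np.ndarray, eigvecs: np.ndarray,
              eigvals: np.ndarray):
    """Generalised least squares given V = U diag(d) U'.

    Returns beta_hat = (X'V^-1 X)^-1 X'V^-1 y and its covariance
    (X'V^-1 X)^-1, computed in the eigenbasis without forming V^-1.
    """
    if np.any(eigvals <= 0):
        raise LmmError("covariance matrix is not positive definite")
    isr = 1.0 / np.sqrt(eigvals)
    xs = (eigvecs.T @ X) * isr[:, None]
    ys = (eigvecs.T @ y) * isr
    g = xs.T @ xs
    sign, _ = np.linalg.slogdet(g)
    if sign <= 0 or np.linalg.cond(g) > 1e12:
        raise LmmError("X' V^-1 X is singular")
    cov = np.linalg.inv(g)
    beta = cov @ (xs.T @ ys)
    return beta, cov


def estimate_bv(
    design: DesignSystem,
    K: KinshipMatrix,
    vc: VarianceComponents,
    full_kinship: KinshipMatrix | None = None,
) -> pd.Series:
    """BLUP breeding values g_hat = sigma_g^2 K Z' V^-1 (y - X beta_hat).

    With ``full_kinship`` covering unobserved lines as well, their values are
    predicted by kinship-block regression on the observed lines' BLUPs.
    """
    ids = list(design.line_ids)
    if list(K.line_ids) != ids:
        raise LmmError("kinship matrix is not aligned to the design's lines")
    if vc.sigma_g2 == 0.0:
        g_obs = np.zeros(len(ids))
    else:
        d_h, u_h = _eigen_h(design.Z, K.values)
        v_eigvals = vc.sigma_g2 * d_h + vc.sigma_e2
        r = design.y - design.X @ vc.beta_hat
        vinv_r = u_h @ ((u_h.T @ r) / v_eigvals)
        g_obs = vc.sigma_g2 * (K.values @ (design.Z.T @ vinv_r))
    out = pd.Series(g_obs, index=ids, name="bv")

    if full_kinship is not None:
        fidx = {lid: i for i, lid in enumerate(full_kinship.line_ids)}
        unobs = [l for l in design.unobserved_line_ids if l in fidx]
        if unobs:
            missing = [l for l in ids if l not in fidx]
            if missing:
                raise LmmError(f"full kinship missing observed lines: {missing}")
            oi = np.array([fidx[l] for l in ids])
            ui = np.array([fidx[l] for l in unobs])
            k_oo = full_kinship.values[np.ix_(oi, oi)]
            k_uo = full_kinship.values[np.ix_(ui, oi)]
            if vc.sigma_g2 == 0.0:
                g_un = np.zeros(len(unobs))
            else:
                g_un = k_uo @ np.linalg.pinv(k_oo) @ g_obs
            out = pd.concat([out, pd.Series(g_un, index=unobs, name="bv")])
    return out
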