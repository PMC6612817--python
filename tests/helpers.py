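"""Shared fixtures-by-function and independent oracles for the test suite.

The oracles deliberately take the dense, explicit-inverse route (full V
inversion, mixed-model equations, brute-force threshold sweeps) so they
stay independent of the eigendecomposition paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from repgwas.io_formats import GenotypeMatrix, KinshipMatrix, PhenotypeTable


def make_geno(rng: np.random.Generator, n: int, m: int,
              n_chrom: int = 2) -> GenotypeMatrix:
    """Random polymorphic genotype matrix with a simple map."""
    freqs = rng.uniform(0.2, 0.8, m)
    codes = rng.binomial(2, freqs, size=(n, m)).astype(np.int16)
    # force polymorphism so kinship is always defined
    for j in range(m):
        if np.ptp(codes[:, j]) == 0:
            codes[0, j] = (codes[0, j] + 1) % 3
    line_ids = [f"L{i:03d}" for i in range(n)]
    marker_ids = [f"M{j:04d}" for j in range(m)]
    chrom = (np.arange(m) * n_chrom) // m + 1
    gmap = pd.DataFrame({"marker": marker_ids, "chrom": chrom.astype(str),
                         "pos": np.arange(1, m + 1)})
    return GenotypeMatrix(line_ids, marker_ids, codes, gmap)


def make_pheno(rng: np.random.Generator, line_ids, k: int = 1,
               n_factors: int = 0) -> PhenotypeTable:
    """Random phenotype with k replications per line and optional factors."""
    rows = []
    for lid in line_ids:
        for r in range(k):
            rows.append({"line": lid, "trait": float(rng.standard_normal()),
                         "env": f"E{r % 2 + 1}", "x": float(rng.uniform())})
    df = pd.DataFrame(rows)
    schema = {}
    if n_factors >= 1:
        schema["env"] = "categorical"
    if n_factors >= 2:
        schema["x"] = "numerical"
    keep = ["line", "trait"] + list(schema)
    return PhenotypeTable(df[keep].copy(), schema)


def random_instance(seed: int, n_lines: int = 30, k: int = 2,
                    n_factors: int = 1, n_markers: int = 50,
                    h2: float = 0.5):
    """A small replicated study with genuine genetic signal for oracle tests."""
    rng = np.random.default_rng(seed)
    geno = make_geno(rng, n_lines, n_markers)
    from repgwas.kinship import compute_kinship

    kin = compute_kinship(geno)
    pheno = make_pheno(rng, geno.line_ids, k=k, n_factors=n_factors)
    # overwrite the trait with a mixed-model draw at heritability h2
    n = n_lines
    chol = np.linalg.cholesky(kin.values + 1e-8 * np.eye(n))
    g = chol @ rng.standard_normal(n)
    g *= math.sqrt(h2 / max(np.var(g), 1e-12))
    e = rng.standard_normal(len(pheno.data)) * math.sqrt(1 - h2)
    per_line = {lid: g[i] for i, lid in enumerate(geno.line_ids)}
    y = np.array([per_line[l] for l in pheno.data["line"]]) + e
    if n_factors >= 1:
        y = y + (pheno.data["env"].to_numpy() == "E2") * 0.7
    if n_factors >= 2:
        y = y + 0.5 * pheno.data["x"].to_numpy()
    pheno.data["trait"] = y
    return pheno, geno, kin


# ---------------------------------------------------------------- oracles


def reml_loglik_dense(y, X, Z, Kv, sg2, se2) -> float:
    """Textbook restricted log-likelihood by explicit inversion."""
    n, p = X.shape
    V = sg2 * (Z @ Kv @ Z.T) + se2 * np.eye(n)
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    XtViX = XtVi @ X
    beta = np.linalg.solve(XtViX, XtVi @ y)
    r = y - X @ beta
    _, ld_v = np.linalg.slogdet(V)
    _, ld_xvx = np.linalg.slogdet(XtViX)
    _, ld_xx = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - p) * math.log(2 * math.pi) + ld_v + ld_xvx - ld_xx
                   + float(r @ Vi @ r))


def reml_oracle(y, X, Z, Kv, n_grid: int = 400):
    """Brute-force REML: dense grid over log delta plus bounded refinement,
    evaluating the restricted likelihood with explicit V inversion."""
    n, p = X.shape
    H = Z @ Kv @ Z.T

    def profile(logd):
        d = math.exp(logd)
        V0 = H + d * np.eye(n)
        Vi = np.linalg.inv(V0)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        sg2 = float(r @ Vi @ r) / (n - p)
        return sg2, reml_loglik_dense(y, X, Z, Kv, sg2, sg2 * d)

    def neg(logd):
        return -profile(logd)[1]

    grid = np.linspace(-10, 10, n_grid)
    vals = [neg(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    logd = float(res.x) if res.fun <= vals[i] else float(grid[i])
    sg2, ll = profile(logd)
    return sg2, sg2 * math.exp(logd), ll


def gls_oracle(y, X, V):
    """Explicit-inverse GLS estimate and covariance."""
    Vi = np.linalg.inv(V)
    cov = np.linalg.inv(X.T @ Vi @ X)
    beta = cov @ (X.T @ Vi @ y)
    return beta, cov


def mme_oracle(y, X, Z, Kv, sg2, se2):
    """Breeding values from Henderson's mixed-model equations, assembled
    and solved densely (requires invertible K)."""
    lam = se2 / sg2
    Kinv = np.linalg.inv(Kv)
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Kinv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    p = X.shape[1]
    return sol[:p], sol[p:]


def roc_sweep_oracle(p_values, truth):
    """Threshold sweep over all distinct P-values plus the endpoints."""
    p = np.asarray(p_values, float)
    t = np.asarray(truth, bool)
    n_pos = t.sum()
    n_neg = (~t).sum()
    pts = [(0.0, 0.0)]
    for thr in np.unique(p):
        called = p <= thr
        pts.append(((called & ~t).sum() / n_neg, (called & t).sum() / n_pos))
    return np.array(sorted(set(pts)))


def auc_pairs_oracle(p_values, truth):
    """Pr(random QTL p < random null p) + 0.5 Pr(equal), by exhaustive pairs."""
    p = np.asarray(p_values, float)
    t = np.asarray(truth, bool)
    pos = p[t]
    neg = p[~t]
    wins = sum((pp < nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))
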