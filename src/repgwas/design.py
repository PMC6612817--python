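"""Build the observation-level model y = X beta + Z g + e.

Replicated phenotype records (years, locations, replications, environments)
are mapped onto their genotyped lines through a 0/1 incidence matrix Z, so
that all observations of a line share one genetic effect; fixed factors and
optional principal-component stratification covariates enter X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeMatrix, PhenotypeTable

__all__ = [
    "DesignError",
    "DesignSystem",
    "StratificationScores",
    "build_design",
    "compute_pcs",
    "marker_observation_vector",
    "line_marker_matrix",
]

RANK_TOL = 1e-10


class DesignError(ValueError):
    """Raised when a model design cannot be constructed."""


@dataclass
class DesignSystem:
    """The (y, X, Z) triple with its row/column bookkeeping.

    ``line_ids`` are the columns of Z (lines with at least one observation,
    in genotype-file order); ``unobserved_line_ids`` are genotyped lines
    without phenotype records, excluded from Z but available for
    kinship-based breeding-value prediction.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    obs_line_ids: np.ndarray
    line_ids: list[str]
    unobserved_line_ids: list[str]
    fixed_effect_names: list[str]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def replication_counts(self) -> np.ndarray:
        return self.Z.sum(axis=0).astype(int)


@dataclass
class StratificationScores:
    """Principal-component scores of the centered genotype matrix (Q)."""

    line_ids: list[str]
    pcs: np.ndarray
    explained_variance: np.ndarray


def compute_pcs(geno: GenotypeMatrix, q: int) -> StratificationScores:
    """Population-stratification PCs of the column-centered, unscaled codes.

    Sign convention: the largest-magnitude marker loading of each component
    is positive, making scores deterministic across runs.
    """
    n, m = geno.codes.shape
    if q < 0:
        raise DesignError("number of PCs must be non-negative")
    if q >= min(n, m):
        raise DesignError(f"q={q} must be < min(n_lines, n_markers)={min(n, m)}")
    xc = geno.codes.astype(float)
    xc -= xc.mean(axis=0)
    if not np.any(np.abs(xc) > 0):
        raise DesignError("all markers are monomorphic; PCA undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for i in range(q):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            u[:, i] = -u[:, i]
            vt[i] = -vt[i]
    scores = u[:, :q] * s[:q]
    explained = s[:q] ** 2 / max(n - 1, 1)
    return StratificationScores(list(geno.line_ids), scores, explained)


def build_design(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    fixed_factors: tuple[str, ...] = (),
    pcs: StratificationScores | None = None,
    n_pcs: int = 0,
) -> DesignSystem:
    """Assemble y, X and Z from phenotype records and genotyped lines.

    X columns are ordered intercept, then factors in the given order
    (categorical factors reference-coded with the lexicographically first
    level dropped, numerical factors as single columns), then ``n_pcs``
    PC-score columns expanded to observations through line membership.
    """
    obs_lines = pheno.data["line"].to_numpy(str)
    geno_ids = list(geno.line_ids)
    geno_set = set(geno_ids)
    missing = sorted(set(obs_lines) - geno_set)
    if missing:
        raise DesignError(f"phenotype lines absent from genotypes: {missing}")

    observed = set(obs_lines)
    line_ids = [lid for lid in geno_ids if lid in observed]
    unobserved = [lid for lid in geno_ids if lid not in observed]
    col_of = {lid: i for i, lid in enumerate(line_ids)}

    n_obs = len(obs_lines)
    z = np.zeros((n_obs, len(line_ids)))
    z[np.arange(n_obs), [col_of[l] for l in obs_lines]] = 1.0

    y = pheno.data["trait"].to_numpy(float)

    cols: list[np.ndarray] = [np.ones(n_obs)]
    names: list[str] = ["intercept"]
    for f in fixed_factors:
        if f not in pheno.schema:
            raise DesignError(f"factor {f!r} was not declared in the phenotype schema")
        vals = pheno.data[f].to_numpy()
        if pheno.schema[f] == "categorical":
            levels = sorted(np.unique(vals))
            for lev in levels[1:]:  # reference coding, first level dropped
                cols.append((vals == lev).astype(float))
                names.append(f"{f}[{lev}]")
        else:
            cols.append(vals.astype(float))
            names.append(f)

    if n_pcs > 0:
        if pcs is None:
            pcs = compute_pcs(geno, n_pcs)
        if n_pcs > pcs.pcs.shape[1]:
            raise DesignError(
                f"requested {n_pcs} PCs but scores hold {pcs.pcs.shape[1]}"
            )
        pc_of = {lid: i for i, lid in enumerate(pcs.line_ids)}
        missing_pc = [lid for lid in line_ids if lid not in pc_of]
        if missing_pc:
            raise DesignError(f"PC scores missing for lines: {missing_pc}")
        pc_line = pcs.pcs[[pc_of[l] for l in line_ids], :n_pcs]
        pc_obs = z @ pc_line
        for i in range(n_pcs):
            cols.append(pc_obs[:, i])
            names.append(f"PC{i + 1}")

    x = np.column_stack(cols)
    _check_rank(x, names)
    return DesignSystem(
        y=y,
        X=x,
        Z=z,
        obs_line_ids=obs_lines,
        line_ids=line_ids,
        unobserved_line_ids=unobserved,
        fixed_effect_names=names,
    )


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[-1] < RANK_TOL * s[0]:
        null = np.abs(vt[-1])
        offenders = [n for n, w in zip(names, null) if w > 1e-8 * null.max()]
        raise DesignError(
            f"fixed-effect matrix is rank deficient; collinear columns: {offenders}"
        )


def line_marker_matrix(design: DesignSystem, geno: GenotypeMatrix) -> np.ndarray:
    """Genotype codes restricted to the design's lines, in Z-column order."""
    idx = {lid: i for i, lid in enumerate(geno.line_ids)}
    rows = [idx[l] for l in design.line_ids]
    return geno.codes[rows, :].astype(float)


def marker_observation_vector(
    design: DesignSystem, geno: GenotypeMatrix, marker_index: int
) -> np.ndarray:
    """Expand one marker's line-level codes to the observation level (Z w)."""
    if not 0 <= marker_index < geno.n_markers:
        raise IndexError(f"marker index {marker_index} out of range")
    idx = {lid: i for i, lid in enumerate(geno.line_ids)}
    rows = np.array([idx[l] for l in design.obs_line_ids])
    return geno.codes[rows, marker_index].astype(float)
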