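"""Marker-based kinship (genomic relationship) matrix.

The estimator is the centered cross-product (VanRaden) form

    K = W W' / c,    w_ij = x_ij - 2 p_j,    c = 2 * sum_j p_j (1 - p_j)

with p_j the reference-allele frequency estimated from the supplied lines
(mean code / 2).  Monomorphic markers center to zero and are excluded from
the denominator, so K is invariant to appending them.  K is symmetric PSD
by construction and serves as the covariance kernel of the random line
effect in the mixed model; a user-supplied K may replace it.
"""

from __future__ import annotations

import numpy as np

from .io_formats import FormatError, GenotypeMatrix, KinshipMatrix

__all__ = ["compute_kinship", "align_kinship"]


def compute_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    codes = geno.codes.astype(float)
    p = codes.mean(axis=0) / 2.0
    # monomorphic = zero variance among lines (a constant-heterozygote
    # column has p=0.5 yet carries no relationship information)
    poly = np.ptp(codes, axis=0) > 0
    if not poly.any():
        raise FormatError(
            "zero denominator: all markers are monomorphic, kinship undefined"
        )
    w = codes[:, poly] - 2.0 * p[poly]
    c = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    k = (w @ w.T) / c
    k = (k + k.T) / 2.0  # exact symmetry against round-off
    return KinshipMatrix(list(geno.line_ids), k)


def align_kinship(kin: KinshipMatrix, line_ids) -> KinshipMatrix:
    """Subset/reorder K's rows and columns to ``line_ids``."""
    idx = {lid: i for i, lid in enumerate(kin.line_ids)}
    missing = [lid for lid in line_ids if lid not in idx]
    if missing:
        raise FormatError(f"kinship matrix is missing lines: {missing}")
    rows = np.array([idx[l] for l in line_ids])
    return KinshipMatrix(list(line_ids), kin.values[np.ix_(rows, rows)].copy())
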