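"""Readers and writers for the delimited genotype, phenotype and kinship dialect.

All files are plain delimited text (tab or comma, auto-detected from the
header line; mixed delimiters are rejected).  Three inputs are supported:

* genotype file: header = marker IDs, first column = line IDs, cells are
  allele-dosage codes in {0, 1, 2} (count of the reference allele).  A
  companion map file gives per-marker chromosome and 1-based position.
* phenotype file: long format, one observation per row; first column is the
  line ID, one column holds the trait value, remaining columns are factors
  declared either ``categorical`` or ``numerical``.
* kinship file: square symmetric table with identical row and column IDs.

Missing genotype codes are a hard error (imputation is the user's job);
missing phenotype records are dropped with a reported count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypeMatrix",
    "PhenotypeTable",
    "KinshipMatrix",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_kinship",
    "write_kinship",
    "write_association",
    "read_association",
]

VALID_CODES = (0, 2, 1)

FACTOR_KINDS = ("categorical", "numerical")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _detect_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    has_tab = "\t" in header
    has_comma = "," in header
    if has_tab and has_comma:
        raise FormatError(f"{path}: mixed tab/comma delimiters in header")
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise FormatError(f"{path}: could not detect a tab or comma delimiter")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage codes plus the marker map.

    ``codes`` holds reference-allele counts in {0,1,2}; ``map`` is a
    DataFrame with columns ``marker``, ``chrom``, ``pos`` aligned to
    ``marker_ids``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    map: pd.DataFrame

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def validate(self) -> None:
        if self.codes.shape != (self.n_lines, self.n_markers):
            raise FormatError(
                f"genotype shape {self.codes.shape} does not match "
                f"{self.n_lines} lines x {self.n_markers} markers"
            )
        if len(set(self.line_ids)) != self.n_lines:
            raise FormatError("duplicate line IDs")
        if len(set(self.marker_ids)) != self.n_markers:
            raise FormatError("duplicate marker IDs")
        bad = ~np.isin(self.codes, VALID_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid genotype code {self.codes[i, j]!r} for line "
                f"{self.line_ids[i]!r}, marker {self.marker_ids[j]!r}; codes "
                "must be 0/1/2 (users are responsible for imputation)"
            )
        if len(self.map) != self.n_markers:
            raise FormatError("map length does not match marker count")
        if list(self.map["marker"]) != list(self.marker_ids):
            raise FormatError("map marker order does not match genotype columns")
        if (self.map["pos"].to_numpy() < 0).any():
            raise FormatError("negative positions in map")


@dataclass
class PhenotypeTable:
    """Long-format phenotype observations after missing-trait exclusion.

    ``data`` has normalised columns ``line``, ``trait`` plus one column per
    declared factor; ``n_dropped`` counts observations removed because the
    trait value was missing.
    """

    data: pd.DataFrame
    schema: dict[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def levels(self, factor: str) -> list:
        if self.schema.get(factor) != "categorical":
            raise FormatError(f"{factor!r} is not a declared categorical factor")
        return sorted(self.data[factor].unique())


@dataclass
class KinshipMatrix:
    """Symmetric PSD line-by-line genetic relationship matrix."""

    line_ids: list[str]
    values: np.ndarray

    def validate(self, sym_tol: float = 1e-8, psd_tol: float = 1e-8) -> None:
        k = self.values
        if k.shape != (len(self.line_ids), len(self.line_ids)):
            raise FormatError("kinship shape does not match line IDs")
        scale = max(np.abs(k).max(), 1e-300)
        if np.abs(k - k.T).max() > sym_tol * scale:
            raise FormatError("kinship matrix is not symmetric within tolerance")
        w = np.linalg.eigvalsh((k + k.T) / 2.0)
        if w[0] < -psd_tol * max(w[-1], 0.0):
            raise FormatError(
                f"kinship matrix is not positive semidefinite "
                f"(min eigenvalue {w[0]:.3g})"
            )


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Load a genotype table and its marker map.

    Marker order in the map must equal the genotype header order; no
    silent reordering is performed.
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    line_ids = [str(x) for x in df.index]
    marker_ids = [str(x) for x in df.columns]
    if len(set(line_ids)) != len(line_ids):
        dup = pd.Index(line_ids)[pd.Index(line_ids).duplicated()][0]
        raise FormatError(f"{path}: duplicate line ID {dup!r}")
    if len(set(marker_ids)) != len(marker_ids):
        dup = pd.Index(marker_ids)[pd.Index(marker_ids).duplicated()][0]
        raise FormatError(f"{path}: duplicate marker ID {dup!r}")

    raw = df.to_numpy()
    num = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    codes = num.reshape(raw.shape)
    bad = ~np.isin(codes, VALID_CODES) | np.isnan(codes)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: invalid genotype code {raw[i, j]!r} for line "
            f"{line_ids[i]!r}, marker {marker_ids[j]!r}; codes must be 0/1/2 "
            "(users are responsible for imputation)"
        )
    codes = codes.astype(np.int16)

    msep = _detect_delimiter(map_path)
    mp = pd.read_csv(map_path, sep=msep, header=0, dtype=str)
    if mp.shape[1] < 3:
        raise FormatError(f"{map_path}: map needs marker, chrom, pos columns")
    mp = mp.iloc[:, :3].copy()
    mp.columns = ["marker", "chrom", "pos"]
    pos = pd.to_numeric(mp["pos"], errors="coerce")
    if pos.isna().any() or (pos < 0).any():
        raise FormatError(f"{map_path}: positions must be non-negative integers")
    mp["pos"] = pos.astype(np.int64)

    geno = GenotypeMatrix(line_ids, marker_ids, codes, mp)
    geno.validate()
    return geno


def write_genotypes(geno: GenotypeMatrix, path, map_path=None, sep="\t") -> None:
    df = pd.DataFrame(geno.codes, index=geno.line_ids, columns=geno.marker_ids)
    df.index.name = "line"
    df.to_csv(path, sep=sep)
    if map_path is not None:
        geno.map.to_csv(map_path, sep=sep, index=False)


def read_phenotypes(path, schema: dict[str, str], trait: str | None = None) -> PhenotypeTable:
    """Load a long-format phenotype table, dropping missing-trait rows.

    ``schema`` maps factor column names to ``"categorical"`` or
    ``"numerical"``.  The first column is the line ID; ``trait`` names the
    trait column (default: second column).
    """
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least line and trait columns")
    line_col = df.columns[0]
    trait_col = trait if trait is not None else df.columns[1]
    if trait_col not in df.columns:
        raise FormatError(f"{path}: trait column {trait_col!r} not found")
    for name, kind in schema.items():
        if kind not in FACTOR_KINDS:
            raise FormatError(
                f"unknown factor declaration {kind!r} for {name!r}; "
                f"expected one of {FACTOR_KINDS}"
            )
        if name not in df.columns:
            raise FormatError(f"{path}: declared factor {name!r} not found")

    trait_vals = pd.to_numeric(df[trait_col], errors="coerce")
    keep = trait_vals.notna()
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise FormatError(f"{path}: no usable observations (all trait values missing)")
    df = df.loc[keep]
    trait_vals = trait_vals.loc[keep]

    out = pd.DataFrame(
        {"line": df[line_col].astype(str).to_numpy(), "trait": trait_vals.to_numpy(float)}
    )
    for name, kind in schema.items():
        col = df[name]
        if col.isna().any():
            raise FormatError(f"{path}: missing value in factor column {name!r}")
        if kind == "numerical":
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().any():
                raise FormatError(f"{path}: non-numeric value in numerical factor {name!r}")
            out[name] = vals.to_numpy(float)
        else:
            out[name] = col.astype(str).to_numpy()
    out = out.reset_index(drop=True)
    return PhenotypeTable(data=out, schema=dict(schema), n_dropped=n_dropped)


def write_phenotypes(pheno: PhenotypeTable, path, sep="\t") -> None:
    pheno.data.to_csv(path, sep=sep, index=False)


def read_kinship(path) -> KinshipMatrix:
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0, index_col=0)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if row_ids != col_ids:
        raise FormatError(f"{path}: row and column line IDs differ")
    values = df.to_numpy(float)
    kin = KinshipMatrix(row_ids, values)
    kin.validate()
    return kin


def write_kinship(kin: KinshipMatrix, path, sep="\t") -> None:
    df = pd.DataFrame(kin.values, index=kin.line_ids, columns=kin.line_ids)
    df.index.name = "line"
    df.to_csv(path, sep=sep)


ASSOC_COLUMNS = ["marker", "chromosome", "position", "effect", "se", "wald", "p", "p_gc"]


def write_association(table, path, sep="\t") -> None:
    """Write an association table: one row per *tested* marker, map order.

    ``table`` is any object with a ``tested`` DataFrame property carrying
    columns marker/chrom/pos/effect/se/wald/p (and optionally p_gc).
    """
    tested = table.tested
    out = pd.DataFrame(
        {
            "marker": tested["marker"].to_numpy(),
            "chromosome": tested["chrom"].to_numpy(),
            "position": tested["pos"].to_numpy(),
            "effect": tested["effect"].to_numpy(),
            "se": tested["se"].to_numpy(),
            "wald": tested["wald"].to_numpy(),
            "p": tested["p"].to_numpy(),
        }
    )
    if "p_gc" in tested.columns and tested["p_gc"].notna().all():
        out["p_gc"] = tested["p_gc"].to_numpy()
    out.to_csv(path, sep=sep, index=False)


def read_association(path) -> pd.DataFrame:
    sep = _detect_delimiter(path)
    return pd.read_csv(path, sep=sep, header=0)
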