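"""Manhattan and QQ plot data tables and rendering.

The numeric data files are the contract: images are regenerated losslessly
from them.  QQ expected quantiles use the plotting positions (i - 0.5) / M.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationTable

__all__ = ["manhattan_data", "qq_data", "render_plots"]


def _chrom_sort_key(chroms: pd.Series):
    as_num = pd.to_numeric(chroms, errors="coerce")
    if as_num.notna().all():
        return as_num
    return chroms.astype(str)


def manhattan_data(table: AssociationTable, gmap: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-tested-marker -log10 P-values ordered by (chromosome, position).

    Chromosomes sort numerically when every label parses as a number, else
    lexicographically.  Skipped markers are omitted.
    """
    tested = table.tested
    out = pd.DataFrame(
        {
            "marker": tested["marker"].to_numpy(),
            "chromosome": tested["chrom"].to_numpy(),
            "position": tested["pos"].to_numpy(),
            "neglog10_p": -np.log10(tested["p"].to_numpy(float)),
        }
    )
    if table.has_gc:
        out["neglog10_p_gc"] = -np.log10(tested["p_gc"].to_numpy(float))
    out["_ck"] = _chrom_sort_key(out["chromosome"])
    out = out.sort_values(["_ck", "position"], kind="mergesort")
    return out.drop(columns="_ck").reset_index(drop=True)


def qq_data(table: AssociationTable, which: str = "raw") -> pd.DataFrame:
    """Observed vs expected -log10 P-value quantiles, ascending in expected.

    Row i pairs the i-th largest observed P-value with the uniform plotting
    position (M - i + 0.5) / M, both on the -log10 scale.
    """
    if which not in ("raw", "adjusted"):
        raise ValueError(f"which must be 'raw' or 'adjusted', got {which!r}")
    col = "p" if which == "raw" else "p_gc"
    tested = table.tested
    if len(tested) == 0:
        raise ValueError("no tested markers")
    if which == "adjusted" and not table.has_gc:
        raise ValueError("genomic control has not been applied to this table")
    p = np.sort(tested[col].to_numpy(float))[::-1]  # descending p
    m = p.size
    expected = (np.arange(m, 0, -1) - 0.5) / m  # descending quantile
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(p),
        }
    )


def render_plots(
    table: AssociationTable,
    out_dir,
    prefix: str = "assoc",
    images: bool = True,
) -> dict[str, Path]:
    """Write Manhattan/QQ data tables and (optionally) raster images.

    Data files are always written so that deleting the images is
    recoverable; returns the mapping of artifact names to paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = manhattan_data(table)
    qq = qq_data(table, "raw")
    paths = {
        "manhattan_data": out_dir / f"{prefix}_manhattan.tsv",
        "qq_data": out_dir / f"{prefix}_qq.tsv",
    }
    man.to_csv(paths["manhattan_data"], sep="\t", index=False)
    qq.to_csv(paths["qq_data"], sep="\t", index=False)
    if table.has_gc:
        qq_adj = qq_data(table, "adjusted")
        paths["qq_adjusted_data"] = out_dir / f"{prefix}_qq_adjusted.tsv"
        qq_adj.to_csv(paths["qq_adjusted_data"], sep="\t", index=False)

    if images:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(9, 3.2))
        offset = 0.0
        ticks, labels = [], []
        for i, (chrom, grp) in enumerate(man.groupby("chromosome", sort=False)):
            x = offset + grp["position"].to_numpy(float)
            ax.scatter(x, grp["neglog10_p"], s=6,
                       color="C0" if i % 2 == 0 else "C1")
            ticks.append(x.mean() if len(x) else offset)
            labels.append(str(chrom))
            offset = x.max() + 1 if len(x) else offset
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10} p$")
        fig.tight_layout()
        paths["manhattan_image"] = out_dir / f"{prefix}_manhattan.png"
        fig.savefig(paths["manhattan_image"], dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(3.6, 3.6))
        ax.plot(qq["expected_neglog10"], qq["observed_neglog10"], ".",
                ms=3, label="raw")
        if table.has_gc:
            ax.plot(qq_adj["expected_neglog10"], qq_adj["observed_neglog10"],
                    ".", ms=3, label="adjusted")
            ax.legend(frameon=False)
        lim = max(float(qq["expected_neglog10"].max()),
                  float(qq["observed_neglog10"].max()))
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        fig.tight_layout()
        paths["qq_image"] = out_dir / f"{prefix}_qq.png"
        fig.savefig(paths["qq_image"], dpi=120)
        plt.close(fig)
    return paths
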