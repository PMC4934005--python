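"""Sliding-window methylation estimation.

The genome is subdivided into 3-kb windows advanced in 600-bp steps; a
window qualifies when it contains at least 5 CpG sites with read data.  The
window methylation level is the binomial maximum-likelihood estimate — the
pooled methylated-read fraction, i.e. the observation-weighted mean over
the window's sites — with a Wilson score interval attached for reporting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import CpGCallTable

__all__ = ["build_windows", "window_methylation", "pair_windows", "paired_window_stats"]

_GRID_ATTRS = ("size_bp", "step_bp")


def build_windows(
    chrom_sizes: dict[str, int], size_bp: int = 3000, step_bp: int = 600
) -> pd.DataFrame:
    """Sliding windows [k*step, k*step+size) per chromosome.

    The last window is truncated at the chromosome end; a chromosome
    shorter than one window yields the single window [0, L).
    """
    if not (size_bp >= step_bp > 0):
        raise ValueError("require size_bp >= step_bp > 0")
    rows = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        if length < size_bp:
            n_win = 1
        else:
            n_win = int(np.ceil((length - size_bp) / step_bp)) + 1
        starts = np.arange(n_win, dtype=np.int64) * step_bp
        ends = np.minimum(starts + size_bp, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["size_bp"] = size_bp
    out.attrs["step_bp"] = step_bp
    return out


def window_methylation(
    table: CpGCallTable,
    windows: pd.DataFrame,
    min_cpg: int = 5,
    ci_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-window pooled methylation for the qualified windows of a sample.

    A CpG site contributes to every window containing its position (windows
    overlap); qualification counts distinct covered sites, not read
    observations.  Returns columns chrom, start, end, n_cpg, n_obs,
    count_meth, m, ci_low, ci_high, sorted by window.
    """
    df = table.df
    parts = []
    for chrom, wsub in windows.groupby("chrom", sort=False):
        sub = df[df["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(sub["count_meth"].to_numpy())])
        dp = np.concatenate(
            [[0], np.cumsum((sub["count_meth"] + sub["count_unmeth"]).to_numpy())]
        )
        i0 = np.searchsorted(pos, wsub["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos, wsub["end"].to_numpy(), side="left")
        n_cpg = i1 - i0
        keep = n_cpg >= min_cpg
        if not keep.any():
            continue
        meth = cm[i1[keep]] - cm[i0[keep]]
        obs = dp[i1[keep]] - dp[i0[keep]]
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": wsub["start"].to_numpy()[keep],
                    "end": wsub["end"].to_numpy()[keep],
                    "n_cpg": n_cpg[keep],
                    "n_obs": obs,
                    "count_meth": meth,
                }
            )
        )
    if not parts:
        out = pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpg", "n_obs", "count_meth",
                     "m", "ci_low", "ci_high"]
        )
    else:
        out = pd.concat(parts, ignore_index=True)
        out["m"] = out["count_meth"] / out["n_obs"]
        lo, hi = proportion_confint(
            out["count_meth"], out["n_obs"], alpha=ci_alpha, method="wilson"
        )
        out["ci_low"] = np.minimum(lo, out["m"])
        out["ci_high"] = np.maximum(hi, out["m"])
    for k in _GRID_ATTRS:
        out.attrs[k] = windows.attrs.get(k)
    out.attrs["min_cpg"] = min_cpg
    return out


def _check_same_grid(a: pd.DataFrame, b: pd.DataFrame) -> None:
    ga = tuple(a.attrs.get(k) for k in _GRID_ATTRS)
    gb = tuple(b.attrs.get(k) for k in _GRID_ATTRS)
    if None not in ga and None not in gb and ga != gb:
        raise ValueError(
            f"window grids differ: size/step {ga} vs {gb}; "
            "both samples must be windowed on the same grid"
        )


def pair_windows(cell_w: pd.DataFrame, bulk_w: pd.DataFrame) -> pd.DataFrame:
    """Inner join of two samples' qualified windows on (chrom, start, end).

    Rows carry m and n_obs for both sides (suffixes _cell / _bulk).
    Raises when the two tables come from different window grids.
    """
    _check_same_grid(cell_w, bulk_w)
    cols = ["chrom", "start", "end", "n_cpg", "n_obs", "count_meth", "m"]
    pairs = pd.merge(
        cell_w[cols], bulk_w[cols], on=["chrom", "start", "end"],
        suffixes=("_cell", "_bulk"),
    )
    if not len(pairs):
        warnings.warn("no overlapping qualified windows between samples", stacklevel=2)
    for k in _GRID_ATTRS:
        pairs.attrs[k] = cell_w.attrs.get(k)
    return pairs


def paired_window_stats(
    cell: CpGCallTable,
    bulk: CpGCallTable,
    windows: pd.DataFrame,
    min_cpg: int = 5,
) -> pd.DataFrame:
    """Paired qualified windows of a cell and its bulk, with shared-site bulk level.

    In addition to the :func:`pair_windows` columns, each row carries
    ``m_bulk_shared`` — the bulk's pooled methylation over only the CpG
    sites the cell covers in that window.  Low-coverage cells see a subset
    of a window's sites, so this is the correct binomial reference for the
    cell's pooled counts.
    """
    cw = window_methylation(cell, windows, min_cpg=min_cpg)
    bw = window_methylation(bulk, windows, min_cpg=min_cpg)
    pairs = pair_windows(cw, bw)
    shared = pd.merge(
        bulk.df, cell.df[["chrom", "pos"]], on=["chrom", "pos"], how="inner"
    )
    sw = window_methylation(CpGCallTable(bulk.sample_id, shared), windows, min_cpg=1)
    sw = sw.rename(columns={"m": "m_bulk_shared"})
    pairs = pd.merge(
        pairs,
        sw[["chrom", "start", "end", "m_bulk_shared"]],
        on=["chrom", "start", "end"],
        how="left",
    )
    # a paired window always has shared sites unless strand conventions
    # differ; fall back to the full-window bulk level
    pairs["m_bulk_shared"] = pairs["m_bulk_shared"].fillna(pairs["m_bulk"])
    for k in _GRID_ATTRS:
        pairs.attrs[k] = windows.attrs.get(k)
    return pairs
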