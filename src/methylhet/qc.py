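"""Sample-level quality control and accuracy checks.

Covers bisulfite conversion efficiency (from non-CpG cytosines, assumed
unmethylated), global 5mC level and the partially methylated site
fraction, merging single cells into a pseudo-bulk for concordance checks
against the real bulk, and the tissue-specific promoter-panel test that
verifies cell identity (liver-specific promoters should be hypomethylated
in hepatocytes relative to fibroblasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, ttest_ind

from .io import CpGCallTable, FeatureMap
from .windows import pair_windows, window_methylation

__all__ = [
    "conversion_efficiency",
    "QCReport",
    "methylation_summary",
    "merge_cells",
    "merged_vs_bulk",
    "MergedVsBulk",
    "promoter_panel_test",
    "PanelTestResult",
]


def conversion_efficiency(noncpg_calls: pd.DataFrame, floor: float = 98.0) -> tuple[float, bool]:
    """Bisulfite conversion efficiency (%) from non-CpG cytosine calls.

    ``100 * (1 - methylated/total)`` over all non-CpG observations; these
    cytosines are assumed truly unmethylated, so any methylated call is a
    conversion failure.  Returns (efficiency, flagged) with ``flagged``
    True when efficiency falls below ``floor``.
    """
    meth = int(noncpg_calls["count_meth"].sum())
    total = meth + int(noncpg_calls["count_unmeth"].sum())
    if total == 0:
        raise ValueError("no non-CpG observations")
    eff = 100.0 * (1.0 - meth / total)
    return eff, eff < floor


@dataclass
class QCReport:
    sample_id: str
    global_5mC: float
    partial_fraction: float
    n_sites: int
    mean_depth: float


def methylation_summary(
    table: CpGCallTable, partial_low: float = 0.1, partial_high: float = 0.9
) -> QCReport:
    """Global 5mC (%) and the partially methylated site fraction (%).

    A site counts as partial when its observed methylated-read fraction
    lies strictly between ``partial_low`` and ``partial_high``.
    """
    if not table.n_sites:
        raise ValueError("empty call table")
    depth = table.depth
    global_5mc = 100.0 * table.df["count_meth"].sum() / depth.sum()
    level = table.level
    partial = 100.0 * ((level > partial_low) & (level < partial_high)).mean()
    return QCReport(
        table.sample_id,
        float(global_5mc),
        float(partial),
        table.n_sites,
        float(depth.mean()),
    )


def merge_cells(cells: list[CpGCallTable], sample_id: str = "merged") -> CpGCallTable:
    """Sum per-site counts across cells; the site set is the union."""
    if not cells:
        raise ValueError("need at least one cell")
    df = pd.concat([c.df for c in cells], ignore_index=True)
    df = (
        df.groupby(["chrom", "pos"], as_index=False, sort=True)[
            ["count_meth", "count_unmeth"]
        ].sum()
    )
    return CpGCallTable(sample_id, df)


@dataclass
class MergedVsBulk:
    n_windows_used: int
    n_windows_available: int
    pearson_r: float
    mean_abs_diff: float


def merged_vs_bulk(
    merged: CpGCallTable,
    bulk: CpGCallTable,
    windows: pd.DataFrame,
    n_sample: int = 10_000,
    seed: int = 0,
    min_cpg: int = 5,
) -> MergedVsBulk:
    """Concordance of merged single cells with their bulk on sampled windows.

    Draws ``n_sample`` qualified paired windows without replacement (all of
    them when fewer are available) and reports the Pearson correlation of
    window methylation plus the mean absolute difference.
    """
    mw = window_methylation(merged, windows, min_cpg=min_cpg)
    bw = window_methylation(bulk, windows, min_cpg=min_cpg)
    pairs = pair_windows(mw, bw)
    avail = len(pairs)
    if avail == 0:
        raise ValueError("no overlapping qualified windows")
    if avail > n_sample:
        rng = np.random.default_rng(seed)
        pairs = pairs.iloc[rng.choice(avail, size=n_sample, replace=False)]
    r = (
        float(pearsonr(pairs["m_cell"], pairs["m_bulk"]).statistic)
        if len(pairs) > 1
        else float("nan")
    )
    mad = float((pairs["m_cell"] - pairs["m_bulk"]).abs().mean())
    return MergedVsBulk(len(pairs), avail, r, mad)


@dataclass
class PanelTestResult:
    per_sample: pd.DataFrame  # sample_id, group, panel_m, panel_m_per_promoter, n_obs
    t_statistic: float
    p_value: float
    target_group: str
    reference_group: str


def promoter_panel_test(
    sample_tables: dict[str, CpGCallTable],
    groups: dict[str, str],
    panel: FeatureMap,
    target_group: str,
    reference_group: str,
    tail: str = "one",
) -> PanelTestResult:
    """Mean 5mC over a promoter panel per sample, compared between groups.

    Per sample the panel methylation is the observation-weighted mean over
    all panel promoter intervals (the per-promoter-averaged variant is also
    emitted).  Group means are compared with a Welch t-test; the one-tailed
    alternative is that the target group is hypomethylated relative to the
    reference.  Samples without panel coverage are excluded with a warning.
    """
    intervals = panel.df
    if not len(intervals):
        raise ValueError("empty promoter panel")
    if len(intervals) == 1:
        warnings.warn("promoter panel has a single interval; test is low-powered",
                      stacklevel=2)
    rows = []
    for sid, table in sample_tables.items():
        meth = obs = 0
        per_prom = []
        for chrom, sub in table.df.groupby("chrom", sort=False):
            ivs = intervals[intervals["chrom"] == chrom]
            pos = sub["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(sub["count_meth"].to_numpy())])
            dp = np.concatenate(
                [[0], np.cumsum((sub["count_meth"] + sub["count_unmeth"]).to_numpy())]
            )
            i0 = np.searchsorted(pos, ivs["start"].to_numpy(), side="left")
            i1 = np.searchsorted(pos, ivs["end"].to_numpy(), side="left")
            m = cm[i1] - cm[i0]
            d = dp[i1] - dp[i0]
            meth += int(m.sum())
            obs += int(d.sum())
            per_prom.extend((m[d > 0] / d[d > 0]).tolist())
        if obs == 0:
            warnings.warn(f"{sid}: no panel promoter coverage; excluded", stacklevel=2)
            continue
        rows.append(
            {
                "sample_id": sid,
                "group": groups[sid],
                "panel_m": meth / obs,
                "panel_m_per_promoter": float(np.mean(per_prom)),
                "n_obs": obs,
            }
        )
    per_sample = pd.DataFrame(rows)
    a = per_sample.loc[per_sample["group"] == target_group, "panel_m"]
    b = per_sample.loc[per_sample["group"] == reference_group, "panel_m"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples with panel coverage")
    alternative = "less" if tail == "one" else "two-sided"
    res = ttest_ind(a, b, equal_var=False, alternative=alternative)
    return PanelTestResult(
        per_sample, float(res.statistic), float(res.pvalue), target_group, reference_group
    )
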