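"""Per-CpG epivariation calling between a single cell and its bulk.

An epivariation is a methylation difference between one cell and the bulk
population it came from at a single CpG.  A site is assayable (eligible)
when (1) sequencing depth exceeds 5 in both the cell and the bulk and
(2) more than 90 % of the bulk's reads share one methylation pattern; the
site is called an epivariation when additionally (3) more than 3 of the
cell's reads carry the opposite pattern.  All three cut-offs are strict
inequalities and configurable.  The headline frequency is
100 * called / eligible; the variant with all overlapping sites in the
denominator is also reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .io import CpGCallTable

__all__ = ["EpivariationCallSet", "call_epivariations", "sensitivity_scan"]


@dataclass
class EpivariationCallSet:
    """Per-site eligibility/call status plus summary frequencies (in %)."""

    sample_id: str
    sites: pd.DataFrame
    n_overlap: int
    n_eligible: int
    n_called: int

    @property
    def frequency(self) -> float:
        """Percent of eligible sites called (the headline rate)."""
        return 100.0 * self.n_called / self.n_eligible if self.n_eligible else float("nan")

    @property
    def alt_frequency_all_overlap(self) -> float:
        """Percent of all cell/bulk-overlapping sites called."""
        return 100.0 * self.n_called / self.n_overlap if self.n_overlap else float("nan")


def call_epivariations(
    cell: CpGCallTable,
    bulk: CpGCallTable,
    min_depth: int = 5,
    bulk_consistency: float = 0.9,
    min_divergent: int = 3,
) -> EpivariationCallSet:
    """Apply the three-criteria caller at every site covered in both samples.

    The bulk majority pattern is methylated when count_meth > count_unmeth
    and unmethylated when the reverse; an exact 50/50 bulk has no majority
    and the site is ineligible.  ``cell_divergent_reads`` counts cell reads
    opposite to the bulk majority; the retained ``direction`` is "gain"
    when the cell diverges toward methylation and "loss" toward
    unmethylation.
    """
    merged = pd.merge(
        cell.df, bulk.df, on=["chrom", "pos"], suffixes=("_cell", "_bulk"), how="inner"
    )
    if not len(merged):
        raise ValueError("no CpG sites covered in both cell and bulk")
    cm = merged["count_meth_cell"].to_numpy()
    cu = merged["count_unmeth_cell"].to_numpy()
    bm = merged["count_meth_bulk"].to_numpy()
    bu = merged["count_unmeth_bulk"].to_numpy()
    cell_depth = cm + cu
    bulk_depth = bm + bu
    major_is_meth = bm > bu
    major_count = np.maximum(bm, bu)
    major_fraction = major_count / bulk_depth
    divergent = np.where(major_is_meth, cu, cm)
    eligible = (
        (cell_depth > min_depth)
        & (bulk_depth > min_depth)
        & (major_fraction > bulk_consistency)
    )
    called = eligible & (divergent > min_divergent)
    sites = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "cell_depth": cell_depth,
            "bulk_depth": bulk_depth,
            "bulk_major_fraction": major_fraction,
            "cell_divergent_reads": divergent,
            "eligible": eligible,
            "called": called,
            "direction": np.where(major_is_meth, "loss", "gain"),
        }
    )
    return EpivariationCallSet(
        cell.sample_id, sites, len(merged), int(eligible.sum()), int(called.sum())
    )


def sensitivity_scan(
    cell: CpGCallTable,
    bulk: CpGCallTable,
    min_depth_grid=(4, 5, 6),
    bulk_consistency_grid=(0.85, 0.9, 0.95),
    min_divergent_grid=(2, 3, 4),
) -> pd.DataFrame:
    """Epivariation frequency across a grid of criterion settings.

    One row per (min_depth, bulk_consistency, min_divergent) combination;
    used to check that the frequency is stable under slight changes to the
    calling criteria.
    """
    grid = list(product(min_depth_grid, bulk_consistency_grid, min_divergent_grid))
    if not grid:
        raise ValueError("empty parameter grid")
    rows = []
    for md, bc, dv in grid:
        calls = call_epivariations(
            cell, bulk, min_depth=md, bulk_consistency=bc, min_divergent=dv
        )
        rows.append(
            {
                "min_depth": md,
                "bulk_consistency": bc,
                "min_divergent": dv,
                "n_eligible": calls.n_eligible,
                "n_called": calls.n_called,
                "frequency": calls.frequency,
                "alt_frequency_all_overlap": calls.alt_frequency_all_overlap,
            }
        )
    return pd.DataFrame(rows)
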