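"""Feature-stratified methylation heterogeneity.

Cell-to-bulk variance is compared across genomic feature classes (CpG
islands, promoters, exons, introns, UTRs, repeat families, histone-mark
regions).  Coverage and sample-size bias is removed by downsampling each
bin in each cell to a fixed number of read-level CpG observations
(5 by default, pooled across the bin's sites irrespective of whether they
come from one site or many) and then retaining, per bin, the cells with
the highest pre-downsampling coverage (10 by default) so every bin is
measured on the same number of cells at the same effective depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CpGCallTable, FeatureMap
from .windows import window_methylation

__all__ = [
    "annotate_bins",
    "downsample_bin_counts",
    "FeatureVarianceProfile",
    "feature_variance_profile",
]


def annotate_bins(bins: pd.DataFrame, features: FeatureMap) -> pd.DataFrame:
    """Attach feature labels to genomic bins.

    A bin receives every label whose interval overlaps it by >= 1 bp;
    unlabeled bins fall back to "intergenic".  Bins carrying a generic
    "promoter" label are resolved into promoter_CGI / promoter_nonCGI by
    CGI overlap.  Returns the bins with a ``labels`` column (frozenset).
    """
    out = bins[["chrom", "start", "end"]].copy()
    labels = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        labs = set(features.labels_at(chrom, int(start), int(end)))
        if "promoter" in labs:
            labs.discard("promoter")
            labs.add("promoter_CGI" if "CGI" in labs else "promoter_nonCGI")
        labels.append(frozenset(labs))
    out["labels"] = labels
    return out


def downsample_bin_counts(
    table: CpGCallTable,
    bins: pd.DataFrame,
    target_obs: int = 5,
    n_rep: int = 20,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Downsample each bin's pooled observations to a fixed count.

    Per replicate, exactly ``target_obs`` read observations are drawn
    without replacement from the bin's pooled methylated/unmethylated
    reads (hypergeometric); the bin estimate ``m_down`` is the mean
    replicate methylated fraction.  Bins with fewer than ``target_obs``
    observations in this sample are excluded.  Returns columns chrom,
    start, end, n_obs_raw, m_raw, m_down.
    """
    if target_obs < 1 or n_rep < 1:
        raise ValueError("target_obs and n_rep must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    w = window_methylation(table, bins, min_cpg=1)
    w = w[w["n_obs"] >= target_obs].reset_index(drop=True)
    if not len(w):
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_obs_raw", "m_raw", "m_down"]
        )
    meth = w["count_meth"].to_numpy()
    unmeth = (w["n_obs"] - w["count_meth"]).to_numpy()
    draws = rng.hypergeometric(
        meth[:, None], unmeth[:, None], target_obs, size=(len(w), n_rep)
    )
    m_down = draws.mean(axis=1) / target_obs
    return pd.DataFrame(
        {
            "chrom": w["chrom"],
            "start": w["start"],
            "end": w["end"],
            "n_obs_raw": w["n_obs"],
            "m_raw": w["m"],
            "m_down": m_down,
        }
    )


@dataclass
class FeatureVarianceProfile:
    """Per-class heterogeneity relative to the genome average."""

    per_class: pd.DataFrame  # label, n_bins, mean_variance, sd, relative_to_genome
    genome_mean: float
    genome_sd: float
    n_bins_total: int
    per_bin: pd.DataFrame


def feature_variance_profile(
    cell_tables: dict[str, CpGCallTable],
    bulk: CpGCallTable,
    bins: pd.DataFrame,
    features: FeatureMap,
    target_obs: int = 5,
    n_cells: int = 10,
    n_rep: int = 20,
    seed: int = 0,
) -> FeatureVarianceProfile:
    """Feature-stratified cell-to-bulk variance on coverage-equalized bins.

    For every bin, cells are ranked by pre-downsampling observation count
    (ties broken by lexicographic sample_id) and the top ``n_cells`` with
    at least ``target_obs`` observations are retained; bins with fewer
    qualifying cells are dropped.  The bin variance is the mean squared
    deviation of the retained cells' downsampled estimates from the bulk
    level (equal weights — downsampling has equalized the information per
    cell).  Class statistics are means over the bins carrying each label;
    ``relative_to_genome`` divides by the mean over all retained bins.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if len(cell_tables) < n_cells:
        raise ValueError(
            f"need at least n_cells={n_cells} cells, got {len(cell_tables)}"
        )
    ss = np.random.SeedSequence(seed)
    per_cell = {}
    for i, sid in enumerate(sorted(cell_tables)):
        per_cell[sid] = downsample_bin_counts(
            cell_tables[sid], bins, target_obs=target_obs, n_rep=n_rep,
            seed=np.random.SeedSequence(seed, spawn_key=(i,)),
        ).set_index(["chrom", "start", "end"])
    bulk_w = window_methylation(bulk, bins, min_cpg=1).set_index(
        ["chrom", "start", "end"]
    )
    annotated = annotate_bins(bins, features)
    rows = []
    for chrom, start, end, labs in zip(
        annotated["chrom"], annotated["start"], annotated["end"], annotated["labels"]
    ):
        key = (chrom, start, end)
        if key not in bulk_w.index:
            continue
        candidates = []
        for sid in sorted(per_cell):
            sub = per_cell[sid]
            if key in sub.index:
                rec = sub.loc[key]
                candidates.append((int(rec["n_obs_raw"]), sid, float(rec["m_down"])))
        if len(candidates) < n_cells:
            continue
        # highest coverage first; ties by sample_id so output is reproducible
        candidates.sort(key=lambda t: (-t[0], t[1]))
        kept = candidates[:n_cells]
        m_bulk = float(bulk_w.loc[key, "m"])
        dev = np.array([m for _, _, m in kept]) - m_bulk
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "labels": labs,
                "m_bulk": m_bulk,
                "variance": float(np.mean(dev**2)),
            }
        )
    per_bin = pd.DataFrame(rows)
    if not len(per_bin):
        raise ValueError(
            "no bin retained: fewer than n_cells cells reach target_obs anywhere"
        )
    genome_mean = float(per_bin["variance"].mean())
    genome_sd = float(per_bin["variance"].std(ddof=1)) if len(per_bin) > 1 else 0.0
    all_labels = sorted({lab for labs in per_bin["labels"] for lab in labs})
    cls_rows = []
    for lab in all_labels:
        mask = per_bin["labels"].apply(lambda s: lab in s)
        sub = per_bin.loc[mask, "variance"]
        cls_rows.append(
            {
                "label": lab,
                "n_bins": int(mask.sum()),
                "mean_variance": float(sub.mean()),
                "sd": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
                "relative_to_genome": float(sub.mean()) / genome_mean
                if genome_mean > 0
                else float("nan"),
            }
        )
    return FeatureVarianceProfile(
        pd.DataFrame(cls_rows), genome_mean, genome_sd, len(per_bin), per_bin
    )
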