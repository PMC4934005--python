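"""Cell-vs-bulk methylation heterogeneity with downsampling noise correction.

A single cell's global heterogeneity is the weighted variance of its window
methylation around the bulk's, with the bulk standing in for the population
mean.  Sparse single-cell coverage alone produces variance, so the
technical-noise floor is estimated by repeatedly downsampling the bulk's own
reads to the cell's exact per-site depth profile and re-measuring the same
variance; the corrected variance is raw minus noise, floored at zero.
Group differences are tested by permutation on per-cell corrected
variances, and per-window differences are flagged as differentially
methylated windows (DMWs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .io import CpGCallTable, SampleManifest
from .windows import paired_window_stats

__all__ = [
    "weighted_variance",
    "downsample_bulk_to_cell",
    "estimate_noise",
    "NoiseEstimate",
    "HeterogeneityProfile",
    "heterogeneity_profile",
    "permutation_test_mean",
    "DMWResult",
    "call_dmws",
]


def weighted_variance(pairs: pd.DataFrame, weight_col: str = "n_obs_cell") -> float:
    """Weighted variance of cell window methylation around the bulk's.

    ``sum_j w_j (m_cell_j - m_bulk_j)^2 / sum_j w_j`` with weights the
    cell's read observations per window — the cell side carries the
    information, bulk depth being much larger.
    """
    if not len(pairs):
        raise ValueError("need at least one paired window")
    w = pairs[weight_col].to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    d = pairs["m_cell"].to_numpy() - pairs["m_bulk"].to_numpy()
    return float(np.sum(w * d * d) / total)


def downsample_bulk_to_cell(
    bulk: CpGCallTable,
    cell: CpGCallTable,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> CpGCallTable:
    """A pseudo-cell: the bulk's reads downsampled to the cell's depth profile.

    At each site present in both samples, the cell's depth is drawn without
    replacement from the bulk's reads (hypergeometric); where the bulk is
    shallower than the cell the bulk site is copied as-is.  The pseudo-cell
    therefore matches the cell's covered-site set and per-site depths, so
    its variance against the bulk is a pure sampling-noise measurement.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    merged = pd.merge(
        bulk.df,
        cell.df[["chrom", "pos", "count_meth", "count_unmeth"]],
        on=["chrom", "pos"],
        suffixes=("_bulk", "_cell"),
        how="inner",
    )
    bm = merged["count_meth_bulk"].to_numpy()
    bu = merged["count_unmeth_bulk"].to_numpy()
    target = (merged["count_meth_cell"] + merged["count_unmeth_cell"]).to_numpy()
    bdepth = bm + bu
    draw = np.minimum(target, bdepth)
    meth = rng.hypergeometric(bm, bu, draw)
    take_bulk = bdepth < target
    depth_out = np.where(take_bulk, bdepth, target)
    meth_out = np.where(take_bulk, bm, meth)
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "count_meth": meth_out,
            "count_unmeth": depth_out - meth_out,
        }
    )
    return CpGCallTable(f"{cell.sample_id}~pseudo", out)


@dataclass
class NoiseEstimate:
    noise_var: float
    replicates: np.ndarray


def estimate_noise(
    bulk: CpGCallTable,
    cell: CpGCallTable,
    windows: pd.DataFrame,
    n_rep: int = 20,
    seed: int | np.random.SeedSequence = 0,
    min_cpg: int = 5,
) -> NoiseEstimate:
    """Technical-noise variance from repeated bulk downsampling.

    Mean over ``n_rep`` replicates of the weighted variance between a
    pseudo-cell (bulk downsampled to the cell's depth profile) and the
    bulk; replicate values are retained for dispersion reporting.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_rep)
    for r in range(n_rep):
        pseudo = downsample_bulk_to_cell(bulk, cell, rng)
        pairs = paired_window_stats(pseudo, bulk, windows, min_cpg=min_cpg)
        if not len(pairs):
            raise ValueError("no qualified pseudo-cell windows; cannot estimate noise")
        reps[r] = weighted_variance(pairs)
    return NoiseEstimate(float(reps.mean()), reps)


@dataclass
class HeterogeneityProfile:
    sample_id: str
    raw_var: float
    noise_var: float
    corrected_var: float
    n_windows: int
    noise_fraction: float


def heterogeneity_profile(
    manifest: SampleManifest,
    tables: dict[str, CpGCallTable],
    windows: pd.DataFrame,
    n_rep: int = 20,
    seed: int = 0,
    min_cpg: int = 5,
) -> pd.DataFrame:
    """Raw, noise and corrected variance for every cell in the manifest.

    Corrected variance is floored at zero (negative estimates are
    Monte-Carlo artifacts of the noise subtraction).  Per-cell failures
    are recorded in the ``error`` column and do not stop other cells.
    """
    rows = []
    for k, row in enumerate(manifest.cells.itertuples()):
        rec: dict = {"sample_id": row.sample_id, "group": row.group, "error": ""}
        try:
            cell = tables[row.sample_id]
            bulk = tables[row.bulk_id]
            pairs = paired_window_stats(cell, bulk, windows, min_cpg=min_cpg)
            raw = weighted_variance(pairs)
            noise = estimate_noise(
                bulk, cell, windows, n_rep=n_rep,
                seed=np.random.SeedSequence(seed, spawn_key=(k,)), min_cpg=min_cpg,
            )
            rec.update(
                raw_var=raw,
                noise_var=noise.noise_var,
                corrected_var=max(raw - noise.noise_var, 0.0),
                n_windows=len(pairs),
                noise_fraction=noise.noise_var / raw if raw > 0 else np.nan,
            )
        except Exception as exc:  # noqa: BLE001 - per-cell isolation
            rec["error"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def permutation_test_mean(
    group_a,
    group_b,
    tail: str = "one",
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "auto",
) -> float:
    """Permutation test on the difference of group means.

    Statistic: mean(A) - mean(B).  When the number of distinct relabelings
    C(|A|+|B|, |A|) is at most ``n_perm`` the null distribution is
    enumerated exhaustively and p = count/total (the observed split is one
    of the enumerated splits, so p >= 1/total); otherwise ``n_perm``
    Monte-Carlo relabelings are drawn and the add-one convention
    p = (count+1)/(n_perm+1) avoids p = 0.  ``method`` forces one path
    ("exhaustive" / "monte-carlo") instead of the size-based "auto"
    choice.  One-tailed tests P(stat >= observed); two-tailed tests
    P(|stat| >= |observed|).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if method not in ("auto", "exhaustive", "monte-carlo"):
        raise ValueError("method must be auto, exhaustive or monte-carlo")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    tol = 1e-12
    exhaustive = (
        method == "exhaustive"
        or (method == "auto" and comb(n, na) <= n_perm)
    )
    if exhaustive:
        total = 0
        count = 0
        idx = np.arange(n)
        for picked in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(picked)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            if tail == "two":
                hit = abs(stat) >= abs(obs) - tol
            else:
                hit = stat >= obs - tol
            count += bool(hit)
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = perm[:na].mean() - perm[na:].mean()
        if tail == "two":
            count += abs(stat) >= abs(obs) - tol
        else:
            count += stat >= obs - tol
    return (count + 1) / (n_perm + 1)


@dataclass
class DMWResult:
    sample_id: str
    dmw_count: int
    tested_count: int
    dmw_frequency: float
    table: pd.DataFrame


def call_dmws(
    pairs: pd.DataFrame,
    effect_min: float = 0.3,
    alpha: float = 0.05,
    sample_id: str = "",
) -> DMWResult:
    """Flag differentially methylated windows for one cell-bulk pairing.

    A window is a DMW iff |m_cell - m_bulk| >= ``effect_min`` and the
    two-sided binomial test of the cell's pooled window counts rejects
    after Benjamini-Hochberg correction at ``alpha`` across all tested
    windows.  The binomial null probability is the bulk's methylation over
    the CpG sites the cell covers in the window (``m_bulk_shared`` from
    :func:`methylhet.windows.paired_window_stats`) so that site-composition
    sampling in sparse cells does not masquerade as a methylation change;
    the effect size keeps the full-window bulk level.
    """
    tested = len(pairs)
    if tested == 0:
        return DMWResult(sample_id, 0, 0, float("nan"), pairs.copy())
    p_null = (
        pairs["m_bulk_shared"] if "m_bulk_shared" in pairs.columns else pairs["m_bulk"]
    ).to_numpy(dtype=float)
    p_null = np.clip(p_null, 0.0, 1.0)
    k = pairs["count_meth_cell"].to_numpy(dtype=int)
    n = pairs["n_obs_cell"].to_numpy(dtype=int)
    pvals = np.array(
        [binomtest(ki, ni, pi, alternative="two-sided").pvalue
         for ki, ni, pi in zip(k, n, p_null)]
    )
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    effect = (pairs["m_cell"] - pairs["m_bulk"]).to_numpy()
    is_dmw = reject & (np.abs(effect) >= effect_min)
    table = pairs[["chrom", "start", "end", "m_cell", "m_bulk"]].copy()
    table["effect"] = effect
    table["p_value"] = pvals
    table["p_adjusted"] = p_adj
    table["is_dmw"] = is_dmw
    n_dmw = int(is_dmw.sum())
    return DMWResult(sample_id, n_dmw, tested, n_dmw / tested, table)
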