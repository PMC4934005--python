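"""Synthetic single-cell / bulk methylome generator with known ground truth.

The generator emulates the statistical structure single-cell whole-genome
bisulfite data is assumed to have: a bimodal bulk methylome in which almost
every CpG is fully methylated or fully unmethylated and a small fraction is
partially methylated; single cells derived from the bulk by independent
per-site epivariation switches; deep bulk coverage versus sparse, shallow
single-cell coverage; and a small bisulfite conversion-failure rate that is
observable at non-CpG cytosines.  Every sample carries its ground truth, so
each downstream estimator can be checked for parameter recovery.

All randomness flows from the single master seed through per-purpose
``numpy.random.SeedSequence`` spawn keys, so adding a sample never changes
previously generated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CpGCallTable,
    FeatureMap,
    SampleManifest,
    write_bismark_coverage,
    write_features,
    write_manifest,
)

__all__ = [
    "SimulationConfig",
    "TrueMethylome",
    "CellTruth",
    "build_synthetic_genome",
    "simulate_bulk_truth",
    "simulate_cell_truth",
    "simulate_calls",
    "epsilon_by_feature",
    "simulate_dataset",
    "SimulatedDataset",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic methylome.

    Defaults describe a mouse-liver-like experiment: CpGs every ~100 bp,
    ~70 % of sites methylated, ~1.07 % partially methylated with levels
    drawn from Beta(5, 5), a 3.3 % per-site epivariation probability per
    cell, 30x bulk depth against sparse single cells (20 % of sites
    covered at ~2x), and a 1.5 % conversion-failure rate (98.5 %
    bisulfite conversion efficiency).
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    cpg_spacing_mean: float = 100.0
    p_methylated: float = 0.7
    f_partial: float = 0.0107
    partial_shape: tuple[float, float] = (5.0, 5.0)
    epsilon: float = 0.033
    bulk_depth_mean: float = 30.0
    cell_depth_mean: float = 2.0
    cell_site_coverage_prob: float = 0.2
    conv_fail: float = 0.015
    n_noncpg_sites: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_methylated", "f_partial", "epsilon",
                     "cell_site_coverage_prob", "conv_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.bulk_depth_mean <= 0 or self.cell_depth_mean <= 0:
            raise ValueError("depth means must be > 0")
        if self.chrom_length_bp <= self.cpg_spacing_mean:
            raise ValueError("chrom_length_bp must exceed cpg_spacing_mean")
        if min(self.partial_shape) <= 0:
            raise ValueError("partial_shape parameters must be > 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class TrueMethylome:
    """Ground-truth bulk methylation: per site a state and a true level.

    ``state`` is one of methylated / unmethylated / partial; ``true_level``
    is the probability a read from the site is methylated (1, 0, or a
    partial draw strictly inside (0, 1)).
    """

    df: pd.DataFrame  # chrom, pos, state, true_level

    def __post_init__(self) -> None:
        df = self.df
        partial = df["state"] == "partial"
        inside = (df["true_level"] > 0) & (df["true_level"] < 1)
        if not (partial == inside).all():
            raise ValueError("state=partial must coincide with 0 < true_level < 1")
        for _, sub in df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError("positions must be strictly increasing per chromosome")


@dataclass
class CellTruth:
    """A single cell's ground truth derived from its bulk.

    Non-partial sites switch state independently with probability epsilon;
    partial sites never switch (the epivariation concept contrasts a
    near-homogeneous bulk with a divergent cell, and partial bulk sites are
    never homogeneous).
    """

    bulk: TrueMethylome
    df: pd.DataFrame  # chrom, pos, switched, effective_level


# genome layout: a repeating 10-kb cassette of feature blocks; every other
# cassette's promoter carries a CGI (-> promoter_CGI), H3K4me3 sits on
# promoters, H3K36me3 on exons, H3K4me1 marks an enhancer-like block.
_CASSETTE = [
    (0, 1000, ("promoter", "H3K4me3")),
    (1000, 1800, ("exon", "H3K36me3")),
    (1800, 4300, ("intron",)),
    (4300, 5000, ("exon", "H3K36me3")),
    (5000, 5500, ("UTR",)),
    (6000, 7000, ("LINE",)),
    (7000, 7800, ("H3K4me1",)),
    (7800, 8700, ("LTR",)),
    (8700, 9100, ("SINE",)),
]
_CASSETTE_BP = 10_000


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def build_synthetic_genome(config: SimulationConfig) -> tuple[pd.DataFrame, FeatureMap]:
    """Lay down CpG sites and a feature annotation for each chromosome.

    CpG positions follow a renewal process with geometric gaps of the
    configured mean (minimum 2 bp, the width of a CpG).  Features are
    non-overlapping blocks per class tiled along each chromosome with an
    intergenic remainder; promoters alternate CGI / non-CGI.  Deterministic
    given ``config.seed``.
    """
    if config.chrom_length_bp < _CASSETTE_BP:
        raise ValueError(
            f"chromosome length {config.chrom_length_bp} shorter than one "
            f"feature cassette ({_CASSETTE_BP} bp)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    sites = []
    feats = []
    for chrom in _chrom_names(config.n_chromosomes):
        n_max = int(2.5 * config.chrom_length_bp / config.cpg_spacing_mean) + 100
        gaps = rng.geometric(1.0 / config.cpg_spacing_mean, size=n_max)
        gaps = np.maximum(gaps, 2)
        pos = np.cumsum(gaps)
        pos = pos[pos < config.chrom_length_bp - 1]
        sites.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64)}))
        for base in range(0, config.chrom_length_bp - _CASSETTE_BP + 1, _CASSETTE_BP):
            cgi_promoter = (base // _CASSETTE_BP) % 2 == 0
            for s, e, labels in _CASSETTE:
                for lab in labels:
                    if lab == "promoter":
                        lab = "promoter_CGI" if cgi_promoter else "promoter_nonCGI"
                        if cgi_promoter:
                            feats.append((chrom, base + s, base + e, "CGI"))
                    feats.append((chrom, base + s, base + e, lab))
    site_map = pd.concat(sites, ignore_index=True)
    fmap = FeatureMap(pd.DataFrame(feats, columns=["chrom", "start", "end", "label"]))
    return site_map, fmap


def simulate_bulk_truth(site_map: pd.DataFrame, config: SimulationConfig) -> TrueMethylome:
    """Assign each CpG a true state and level, independently per site.

    A site is partial with probability ``f_partial`` (level drawn from
    Beta(partial_shape)), otherwise methylated with probability
    ``p_methylated`` (level 1) or unmethylated (level 0).
    """
    if not len(site_map):
        raise ValueError("empty CpG site map")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    n = len(site_map)
    u = rng.random(n)
    partial = u < config.f_partial
    meth = ~partial & (rng.random(n) < config.p_methylated)
    level = np.where(meth, 1.0, 0.0)
    if partial.any():
        a, b = config.partial_shape
        draws = rng.beta(a, b, size=int(partial.sum()))
        # Beta draws of exactly 0/1 would contradict state=partial
        draws = np.clip(draws, 1e-12, 1 - 1e-12)
        level[partial] = draws
    state = np.where(partial, "partial", np.where(meth, "methylated", "unmethylated"))
    df = site_map.copy()
    df["state"] = state
    df["true_level"] = level
    return TrueMethylome(df)


def simulate_cell_truth(
    bulk: TrueMethylome,
    epsilon: float | np.ndarray,
    seed: int | np.random.SeedSequence,
) -> CellTruth:
    """Derive a single cell's truth by per-site epivariation switches.

    Each non-partial site switches state (methylated <-> unmethylated)
    independently with probability ``epsilon`` (a scalar, or an array with
    one entry per site for feature-stratified switch rates).  Partial
    sites are never switched.
    """
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("epsilon outside [0, 1]")
    rng = np.random.default_rng(seed)
    df = bulk.df
    n = len(df)
    if eps.ndim and len(eps) != n:
        raise ValueError("per-site epsilon array must match site count")
    eligible = (df["state"] != "partial").to_numpy()
    switched = (rng.random(n) < eps) & eligible
    effective = df["true_level"].to_numpy().copy()
    effective[switched] = 1.0 - np.round(effective[switched])
    out = df[["chrom", "pos"]].copy()
    out["switched"] = switched
    out["effective_level"] = effective
    return CellTruth(bulk, out)


def _truncated_poisson(rng: np.random.Generator, mean: float, n: int) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1 (every covered site has a read)."""
    d = rng.poisson(mean, size=n)
    zero = d == 0
    while zero.any():
        d[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = d == 0
    return d


def simulate_calls(
    truth: TrueMethylome | CellTruth,
    kind: str,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    sample_id: str = "sample",
) -> tuple[CpGCallTable, pd.DataFrame]:
    """Emit read-count calls for a sample plus a non-CpG QC table.

    Bulk samples cover every site; cells cover each site independently with
    ``cell_site_coverage_prob``.  Covered-site depth is Poisson (mean per
    kind) truncated at >= 1.  Methylated counts are Binomial(depth, p) with
    p the site's effective level inflated by the conversion-failure rate
    (an unmethylated cytosine reads as methylated with probability
    ``conv_fail``).  The non-CpG table holds ``n_noncpg_sites`` positions
    whose reads are methylated only through conversion failure.
    """
    if kind not in ("bulk", "cell"):
        raise ValueError("kind must be 'bulk' or 'cell'")
    rng = np.random.default_rng(seed)
    df = truth.df
    level = (
        df["effective_level"] if isinstance(truth, CellTruth) else df["true_level"]
    ).to_numpy()
    n = len(df)
    if kind == "cell":
        covered = rng.random(n) < config.cell_site_coverage_prob
        depth_mean = config.cell_depth_mean
    else:
        covered = np.ones(n, dtype=bool)
        depth_mean = config.bulk_depth_mean
    n_cov = int(covered.sum())
    if n_cov == 0:
        warnings.warn(f"{sample_id}: no covered CpG sites", stacklevel=2)
    depth = _truncated_poisson(rng, depth_mean, n_cov)
    p_read = level[covered] + (1.0 - level[covered]) * config.conv_fail
    meth = rng.binomial(depth, p_read)
    calls = pd.DataFrame(
        {
            "chrom": df.loc[covered, "chrom"].to_numpy(),
            "pos": df.loc[covered, "pos"].to_numpy(),
            "count_meth": meth,
            "count_unmeth": depth - meth,
        }
    )
    # non-CpG cytosines: assumed truly unmethylated, used for conversion QC;
    # placed on a dedicated contig so they never collide with CpG sites
    n_nc = config.n_noncpg_sites
    nc_depth = _truncated_poisson(rng, depth_mean, n_nc) if n_nc else np.array([], int)
    nc_meth = rng.binomial(nc_depth, config.conv_fail) if n_nc else np.array([], int)
    noncpg = pd.DataFrame(
        {
            "chrom": "chrNonCpG",
            "pos": np.arange(n_nc, dtype=np.int64) * 3,
            "count_meth": nc_meth,
            "count_unmeth": nc_depth - nc_meth,
        }
    )
    return CpGCallTable(sample_id, calls), noncpg


def epsilon_by_feature(
    site_map: pd.DataFrame,
    features: FeatureMap,
    class_epsilon: dict[str, float],
    default: float,
) -> np.ndarray:
    """Per-site switch probabilities stratified by feature class.

    Each site takes the maximum epsilon among the classes overlapping it
    (so a repeat inside an intron keeps the repeat's rate), or ``default``
    when no listed class overlaps.
    """
    eps = np.full(len(site_map), default, dtype=float)
    for i, (chrom, pos) in enumerate(zip(site_map["chrom"], site_map["pos"])):
        labels = features.labels_at(chrom, int(pos)) & set(class_epsilon)
        if labels:
            eps[i] = max(class_epsilon[lab] for lab in labels)
    return eps


@dataclass
class SimulatedDataset:
    """Everything one simulated experiment produced, truth included."""

    config: SimulationConfig
    site_map: pd.DataFrame
    features: FeatureMap
    bulk_truth: TrueMethylome
    cell_truths: dict[str, CellTruth]
    calls: dict[str, CpGCallTable]
    noncpg: dict[str, pd.DataFrame]
    manifest: SampleManifest


def simulate_dataset(
    config: SimulationConfig,
    n_cells: int,
    group: str = "hepatocyte",
    bulk_id: str = "bulk",
    epsilon: float | np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate one bulk plus ``n_cells`` single cells end to end.

    ``epsilon`` overrides ``config.epsilon`` (scalar or per-site array).
    Per-sample seeds are spawned from the master seed by sample index, so
    sample k is reproducible regardless of how many samples follow it.
    """
    site_map, features = build_synthetic_genome(config)
    bulk_truth = simulate_bulk_truth(site_map, config)
    eps = config.epsilon if epsilon is None else epsilon
    bulk_calls, bulk_nc = simulate_calls(
        bulk_truth, "bulk", config,
        np.random.SeedSequence(config.seed, spawn_key=(2,)), sample_id=bulk_id,
    )
    cell_truths: dict[str, CellTruth] = {}
    calls: dict[str, CpGCallTable] = {bulk_id: bulk_calls}
    noncpg: dict[str, pd.DataFrame] = {bulk_id: bulk_nc}
    rows = [
        {"sample_id": bulk_id, "path": f"{bulk_id}.cov", "kind": "bulk",
         "group": group, "bulk_id": ""}
    ]
    for i in range(n_cells):
        sid = f"{group}_cell{i + 1:02d}"
        ct = simulate_cell_truth(
            bulk_truth, eps, np.random.SeedSequence(config.seed, spawn_key=(10, i, 0))
        )
        c_calls, c_nc = simulate_calls(
            ct, "cell", config,
            np.random.SeedSequence(config.seed, spawn_key=(10, i, 1)), sample_id=sid,
        )
        cell_truths[sid] = ct
        calls[sid] = c_calls
        noncpg[sid] = c_nc
        rows.append(
            {"sample_id": sid, "path": f"{sid}.cov", "kind": "cell",
             "group": group, "bulk_id": bulk_id}
        )
    manifest = SampleManifest(pd.DataFrame(rows))
    return SimulatedDataset(
        config, site_map, features, bulk_truth, cell_truths, calls, noncpg, manifest
    )


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to disk as plain-text fixture files.

    Layout: one Bismark coverage file per sample, one non-CpG coverage file
    per sample, one BED per feature class under ``features/``, a manifest,
    and a ground-truth table.  Reading the coverage files back through the
    io module reproduces the in-memory tables exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "features").mkdir(exist_ok=True)
    (out / "noncpg").mkdir(exist_ok=True)
    written: dict[str, Path] = {}
    for row in dataset.manifest.df.itertuples():
        p = out / row.path
        write_bismark_coverage(dataset.calls[row.sample_id], p)
        written[row.sample_id] = p
        ncp = out / "noncpg" / f"{row.sample_id}.noncpg.cov"
        nc = dataset.noncpg[row.sample_id]
        CpGCallTable(row.sample_id, nc)  # validates
        depth = nc["count_meth"] + nc["count_unmeth"]
        pd.DataFrame(
            {
                "chrom": nc["chrom"],
                "start": nc["pos"] + 1,
                "end": nc["pos"] + 1,
                "pct": (100.0 * nc["count_meth"] / depth.clip(lower=1)).round(2),
                "cm": nc["count_meth"],
                "cu": nc["count_unmeth"],
            }
        ).to_csv(ncp, sep="\t", header=False, index=False, float_format="%.2f")
    for label, sub in dataset.features.df.groupby("label", sort=True):
        write_features(FeatureMap(sub), out / "features" / f"{label}.bed")
    write_features(dataset.features, out / "features.bed")
    write_manifest(dataset.manifest, out / "manifest.tsv")
    truth = dataset.bulk_truth.df.copy()
    for sid, ct in dataset.cell_truths.items():
        truth[f"switched_{sid}"] = ct.df["switched"].to_numpy()
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return written
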