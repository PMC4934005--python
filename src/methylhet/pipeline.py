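"""End-to-end orchestration of the analysis stages.

Stages run in order: (optional) simulate -> qc -> windows -> heterogeneity
(+ group permutation test) -> dmw -> epivariation -> features.  Stages
communicate through tab-separated tables in the output directory so any
stage can be rerun in isolation; the run log echoes every tunable and the
seeds, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .epivariation import call_epivariations
from .features import feature_variance_profile
from .heterogeneity import call_dmws, heterogeneity_profile, permutation_test_mean
from .io import (
    CpGCallTable,
    FeatureMap,
    SampleManifest,
    read_bismark_coverage,
    read_features,
    read_manifest,
)
from .qc import conversion_efficiency, merge_cells, merged_vs_bulk, methylation_summary
from .simdata import SimulationConfig, simulate_dataset, write_fixture
from .windows import build_windows, paired_window_stats, window_methylation

logger = logging.getLogger("methylhet")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with defaults at the published values.

    Windows 3000/600 bp with >= 5 CpGs; epivariation criteria depth > 5,
    bulk consistency > 90 %, divergent reads > 3; feature stratification
    with 5-observation bin downsampling and 10 retained cells.
    """

    out_dir: str = "methylhet_out"
    manifest: str | None = None
    features: str | None = None
    simulate: dict | None = None  # SimulationConfig fields + n_cells, group
    window_size_bp: int = 3000
    window_step_bp: int = 600
    min_cpg: int = 5
    n_rep: int = 20
    epivar_min_depth: int = 5
    epivar_bulk_consistency: float = 0.9
    epivar_min_divergent: int = 3
    dmw_effect_min: float = 0.3
    dmw_alpha: float = 0.05
    feature_target_obs: int = 5
    feature_n_cells: int = 10
    feature_n_rep: int = 20
    qc_partial_low: float = 0.1
    qc_partial_high: float = 0.9
    qc_conv_floor: float = 98.0
    merged_n_sample: int = 10_000
    perm_n: int = 10_000
    perm_tail: str = "one"
    seed: int = 0
    chrom_sizes: dict = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        n_cells = int(sim_kwargs.pop("n_cells", 8))
        group = sim_kwargs.pop("group", "hepatocyte")
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = SimulationConfig(**sim_kwargs)
        ds = simulate_dataset(sim, n_cells=n_cells, group=group)
        write_fixture(ds, out / "fixture")
        logger.info("simulated %d cells + 1 bulk (%d CpG sites)",
                    n_cells, len(ds.site_map))
        chrom_sizes = {
            f"chr{i + 1}": sim.chrom_length_bp for i in range(sim.n_chromosomes)
        }
        return ds.manifest, ds.calls, ds.noncpg, ds.features, chrom_sizes
    if cfg.manifest is None:
        raise ValueError("config needs either 'manifest' or 'simulate'")
    manifest = read_manifest(cfg.manifest)
    base = Path(cfg.manifest).parent
    tables = {}
    noncpg = {}
    for row in manifest.df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        tables[row.sample_id] = read_bismark_coverage(p, sample_id=row.sample_id)
        nc = base / "noncpg" / f"{row.sample_id}.noncpg.cov"
        if nc.exists():
            noncpg[row.sample_id] = read_bismark_coverage(
                nc, sample_id=row.sample_id
            ).df
    features = read_features(cfg.features) if cfg.features else None
    if cfg.chrom_sizes:
        chrom_sizes = dict(cfg.chrom_sizes)
    else:
        sizes: dict[str, int] = {}
        for t in tables.values():
            for chrom, sub in t.df.groupby("chrom", sort=False):
                sizes[chrom] = max(sizes.get(chrom, 0), int(sub["pos"].max()) + 2)
        chrom_sizes = sizes
    return manifest, tables, noncpg, features, chrom_sizes


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Stage tables written: qc.tsv, windows/<sample>.windows.tsv,
    heterogeneity.tsv, permutation_tests.tsv, dmw.tsv, epivariation.tsv,
    feature_variance.tsv, merged_vs_bulk.tsv, and run.log.yaml echoing the
    full configuration.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        manifest, tables, noncpg, features, chrom_sizes = _load_inputs(cfg, out)
        manifest_df = manifest.df

        stage = "qc"
        qc_rows = []
        for row in manifest_df.itertuples():
            rep = methylation_summary(
                tables[row.sample_id], cfg.qc_partial_low, cfg.qc_partial_high
            )
            rec = dataclasses.asdict(rep)
            if row.sample_id in noncpg:
                eff, flagged = conversion_efficiency(
                    noncpg[row.sample_id], floor=cfg.qc_conv_floor
                )
                rec["conversion_efficiency"] = eff
                rec["conversion_flagged"] = flagged
            qc_rows.append(rec)
        pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False)
        logger.info("qc: %d samples", len(qc_rows))

        stage = "windows"
        windows = build_windows(chrom_sizes, cfg.window_size_bp, cfg.window_step_bp)
        (out / "windows").mkdir(exist_ok=True)
        win_tables = {}
        for sid, table in tables.items():
            w = window_methylation(table, windows, min_cpg=cfg.min_cpg)
            win_tables[sid] = w
            w.to_csv(out / "windows" / f"{sid}.windows.tsv", sep="\t", index=False)
            logger.info("windows: %s qualified %d/%d", sid, len(w), len(windows))

        stage = "heterogeneity"
        het = heterogeneity_profile(
            manifest, tables, windows,
            n_rep=cfg.n_rep, seed=cfg.seed, min_cpg=cfg.min_cpg,
        )
        het.to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
        groups = het.loc[het["error"] == "", :].groupby("group")["corrected_var"]
        perm_rows = []
        group_vals = {g: v.to_numpy() for g, v in groups}
        names = sorted(group_vals)
        for i, ga in enumerate(names):
            for gb in names[i + 1:]:
                if len(group_vals[ga]) >= 2 and len(group_vals[gb]) >= 2:
                    p = permutation_test_mean(
                        group_vals[ga], group_vals[gb],
                        tail=cfg.perm_tail, n_perm=cfg.perm_n, seed=cfg.seed,
                    )
                    perm_rows.append({"group_a": ga, "group_b": gb, "p_value": p})
        pd.DataFrame(perm_rows).to_csv(
            out / "permutation_tests.tsv", sep="\t", index=False
        )

        stage = "dmw"
        dmw_rows = []
        for row in manifest.cells.itertuples():
            pairs = paired_window_stats(
                tables[row.sample_id], tables[row.bulk_id], windows,
                min_cpg=cfg.min_cpg,
            )
            res = call_dmws(
                pairs, effect_min=cfg.dmw_effect_min, alpha=cfg.dmw_alpha,
                sample_id=row.sample_id,
            )
            dmw_rows.append(
                {
                    "sample_id": row.sample_id,
                    "group": row.group,
                    "dmw_count": res.dmw_count,
                    "tested_count": res.tested_count,
                    "dmw_frequency": res.dmw_frequency,
                }
            )
        pd.DataFrame(dmw_rows).to_csv(out / "dmw.tsv", sep="\t", index=False)

        stage = "epivariation"
        epi_rows = []
        for row in manifest.cells.itertuples():
            calls = call_epivariations(
                tables[row.sample_id], tables[row.bulk_id],
                min_depth=cfg.epivar_min_depth,
                bulk_consistency=cfg.epivar_bulk_consistency,
                min_divergent=cfg.epivar_min_divergent,
            )
            epi_rows.append(
                {
                    "sample_id": row.sample_id,
                    "group": row.group,
                    "n_overlap": calls.n_overlap,
                    "n_eligible": calls.n_eligible,
                    "n_called": calls.n_called,
                    "frequency_pct": calls.frequency,
                    "alt_frequency_all_overlap_pct": calls.alt_frequency_all_overlap,
                }
            )
            logger.info(
                "epivariation: %s %d/%d eligible sites called (%.3f%%)",
                row.sample_id, calls.n_called, calls.n_eligible, calls.frequency,
            )
        pd.DataFrame(epi_rows).to_csv(out / "epivariation.tsv", sep="\t", index=False)

        stage = "merged_vs_bulk"
        mvb_rows = []
        for bulk_id, cells in manifest.cells.groupby("bulk_id"):
            merged = merge_cells(
                [tables[s] for s in cells["sample_id"]], sample_id=f"merged_{bulk_id}"
            )
            rep = merged_vs_bulk(
                merged, tables[bulk_id], windows,
                n_sample=cfg.merged_n_sample, seed=cfg.seed, min_cpg=cfg.min_cpg,
            )
            mvb_rows.append({"bulk_id": bulk_id, **dataclasses.asdict(rep)})
        pd.DataFrame(mvb_rows).to_csv(out / "merged_vs_bulk.tsv", sep="\t", index=False)

        stage = "features"
        if features is not None:
            bins = build_windows(chrom_sizes, cfg.window_size_bp, cfg.window_size_bp)
            cell_ids = list(manifest.cells["sample_id"])
            bulk_id = manifest.bulks["sample_id"].iloc[0]
            try:
                prof = feature_variance_profile(
                    {s: tables[s] for s in cell_ids},
                    tables[bulk_id],
                    bins,
                    features,
                    target_obs=cfg.feature_target_obs,
                    n_cells=cfg.feature_n_cells,
                    n_rep=cfg.feature_n_rep,
                    seed=cfg.seed,
                )
                cls = prof.per_class.copy()
                cls.loc[len(cls)] = {
                    "label": "genome_average",
                    "n_bins": prof.n_bins_total,
                    "mean_variance": prof.genome_mean,
                    "sd": prof.genome_sd,
                    "relative_to_genome": 1.0,
                }
                cls.to_csv(out / "feature_variance.tsv", sep="\t", index=False)
            except ValueError as exc:
                logger.warning("features stage skipped: %s", exc)
        else:
            logger.info("features stage skipped: no feature annotation")

        stage = "log"
        with open(out / "run.log.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "methylhet_version": __version__,
                    "config": dataclasses.asdict(cfg),
                    "n_samples": len(manifest_df),
                    "n_windows": len(windows),
                },
                fh,
                sort_keys=True,
            )
    except Exception:
        logger.error("pipeline failed at stage %r (partial outputs kept in %s)",
                     stage, out)
        raise
    return out
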