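"""Noise-corrected cell-vs-bulk variance and a group permutation test.

Simulates a high-heterogeneity group (hepatocyte-like, per-site switch
probability 0.033) and a low-heterogeneity group (fibroblast-like, 0.008),
each with its own bulk; quantifies each cell's weighted variance against
its bulk, estimates the technical-noise floor by downsampling the bulk to
the cell's depth profile, and tests the group difference in corrected
variance by permutation.
"""

import pandas as pd

import methylhet as mh

windows = mh.build_windows({"chr1": 800_000})
profiles = []
for group, eps, seed in (("hepatocyte", 0.033, 1), ("fibroblast", 0.008, 2)):
    cfg = mh.SimulationConfig(
        n_chromosomes=1, chrom_length_bp=800_000,
        cell_site_coverage_prob=0.5, epsilon=eps, seed=seed,
    )
    ds = mh.simulate_dataset(cfg, n_cells=4, group=group, bulk_id=f"bulk_{group}")
    prof = mh.heterogeneity_profile(ds.manifest, ds.calls, windows, n_rep=10, seed=3)
    profiles.append(prof)
prof = pd.concat(profiles, ignore_index=True)

cols = ["sample_id", "group", "raw_var", "noise_var", "corrected_var", "n_windows"]
print(prof[cols].to_string(index=False, float_format=lambda x: f"{x:.5f}"))

hep = prof.loc[prof["group"] == "hepatocyte", "corrected_var"]
fib = prof.loc[prof["group"] == "fibroblast", "corrected_var"]
p = mh.permutation_test_mean(hep, fib, tail="one", n_perm=10_000, seed=4)
print(f"\none-tailed permutation test, hepatocyte > fibroblast: p = {p:.4f}")
# corrected variance (raw minus downsampling noise) separates the two
# groups; the permutation p at 4+4 cells is exhaustive over C(8,4) splits
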