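"""Per-CpG epivariation calling and criterion robustness.

A cell is generated with a known 3.3 % per-site switch probability and
deep-ish coverage; the three-criteria caller (depth > 5 in cell and bulk,
bulk consistency > 90 %, > 3 divergent cell reads) recovers the rate, and
a sensitivity scan shows the estimate is stable under slight criterion
changes.
"""

import methylhet as mh

cfg = mh.SimulationConfig(
    n_chromosomes=1, chrom_length_bp=2_000_000, f_partial=0.0, conv_fail=0.0,
    cell_depth_mean=10.0, cell_site_coverage_prob=1.0, n_noncpg_sites=0, seed=5,
)
sites, _ = mh.build_synthetic_genome(cfg)
bulk_truth = mh.simulate_bulk_truth(sites, cfg)
cell_truth = mh.simulate_cell_truth(bulk_truth, epsilon=0.033, seed=6)
bulk, _ = mh.simulate_calls(bulk_truth, "bulk", cfg, 7, "bulk")
cell, _ = mh.simulate_calls(cell_truth, "cell", cfg, 8, "cell")

calls = mh.call_epivariations(cell, bulk)
print(f"sites covered in both:  {calls.n_overlap}")
print(f"eligible (assayable):   {calls.n_eligible}")
print(f"called epivariations:   {calls.n_called}")
print(f"frequency (eligible):   {calls.frequency:.2f} %   (truth: 3.30 %)")
print(f"frequency (all overlap): {calls.alt_frequency_all_overlap:.2f} %")

scan = mh.sensitivity_scan(cell, bulk)
print(f"\nscan over 27 criterion combinations: "
      f"{scan['frequency'].min():.2f}-{scan['frequency'].max():.2f} %")
# the recovered rate matches the generating switch probability, and varies
# by well under one percentage point across neighbouring criterion settings
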