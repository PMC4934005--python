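# methylhet

Single-cell whole-genome bisulfite sequencing (scWGBS) reveals how much the
DNA methylome varies from cell to cell within one tissue.  `methylhet` is a
tested, reusable implementation of the analysis that turns sparse per-CpG
read counts from single cells, together with a deep bulk methylome of the
same population, into quantitative heterogeneity estimates:

- **windowed methylation** — 3-kb sliding windows (600-bp step); a window
  qualifies with ≥ 5 covered CpGs and its level is the pooled binomial MLE
  m = Σ meth / Σ reads with a Wilson interval;
- **noise-corrected variance** — per cell, the weighted variance
  V = Σⱼ wⱼ (m_cell,ⱼ − m_bulk,ⱼ)² / Σⱼ wⱼ across paired windows (weights =
  cell read observations), minus a technical-noise floor estimated by
  repeatedly downsampling the bulk's own reads to the cell's exact per-site
  depth profile; group differences tested by permutation on the mean;
- **differentially methylated windows (DMWs)** — effect ≥ 0.3 plus a
  BH-corrected binomial test of the cell's pooled window counts against the
  bulk level at the cell-covered sites;
- **epivariation calling** — a per-CpG methylation difference between one
  cell and its bulk, called when depth > 5 in both samples, > 90 % of bulk
  reads share one pattern, and > 3 cell reads carry the opposite pattern;
  reported as 100 · called / eligible (%);
- **feature stratification** — cell-to-bulk variance per genomic feature
  class (CGI, promoters, exons, introns, UTRs, LINE/LTR/SINE, histone-mark
  regions) on coverage-equalized bins: every bin in every cell is
  downsampled to 5 pooled CpG observations and the 10 highest-coverage
  cells are retained per bin;
- **QC** — bisulfite conversion efficiency from non-CpG cytosines, global
  5mC, partially methylated site fraction, merged-cells-vs-bulk concordance,
  and a tissue-specific promoter-panel identity test (one-tailed Welch t).

Because public scWGBS data are not bundled, the package ships a first-class
synthetic-data module: it generates a bimodal bulk methylome (~1 % partially
methylated sites), derives single cells by independent per-site epivariation
switches with known probability ε, and emits realistic sparse cell coverage
plus non-CpG calls with a controlled conversion-failure rate — so every
estimator is validated by parameter recovery against ground truth.

It is primarily a Python library (`import methylhet`); a thin `methylhet`
CLI exposes each stage (`simulate`, `qc`, `windows`, `het`, `dmw`, `epivar`,
`epivar-scan`, `features`, `panel-test`, `perm-test`, `run-all`) over
Bismark-coverage files, BED feature annotations and a tab-separated sample
manifest.

## Worked example

`examples/04_epivariation.py` simulates a 2-Mb chromosome (~20,000 CpGs,
70 % methylated), a 30× bulk and one cell at ~10× with a known 3.3 %
per-site switch probability, then runs the three-criteria caller:

```
sites covered in both:  19964
eligible (assayable):   18653
called epivariations:   576
frequency (eligible):   3.09 %   (truth: 3.30 %)
frequency (all overlap): 2.89 %

scan over 27 criterion combinations: 3.09-3.14 %
```

The caller recovers the generating switch rate within binomial error
(se ≈ 0.13 points at ~19 k eligible sites), and the estimate moves by well
under one percentage point when the calling criteria are nudged.
`examples/03_heterogeneity.py` shows the variance side: two simulated
groups (ε = 0.033 vs 0.008) separate cleanly in corrected variance after
noise subtraction (one-tailed permutation p = 0.0143 at 4 + 4 cells),
even though raw variances overlap.  The other examples cover fixture
generation, QC/windowing, and feature stratification.

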