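import numpy as np
import pandas as pd
import pytest

import methylhet as mh

from conftest import make_table


class TestConversionEfficiency:
    def test_fully_converted(self):
        nc = pd.DataFrame({"count_meth": [0, 0], "count_unmeth": [50, 50]})
        eff, flagged = mh.conversion_efficiency(nc)
        assert eff == 100.0 and not flagged

    def test_two_failures_in_hundred(self):
        nc = pd.DataFrame({"count_meth": [2], "count_unmeth": [98]})
        eff, flagged = mh.conversion_efficiency(nc)
        assert eff == pytest.approx(98.0)
        assert not flagged  # 98.0 is not below the floor of 98

    def test_below_floor_flagged(self):
        nc = pd.DataFrame({"count_meth": [5], "count_unmeth": [95]})
        assert mh.conversion_efficiency(nc)[1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mh.conversion_efficiency(pd.DataFrame({"count_meth": [], "count_unmeth": []}))

    def test_recovers_simulated_failure_rate(self, small_dataset):
        nc = small_dataset.noncpg["bulk"]
        total = int((nc["count_meth"] + nc["count_unmeth"]).sum())
        eff, flagged = mh.conversion_efficiency(nc)
        se = 100 * np.sqrt(0.015 * 0.985 / total)
        assert abs(eff - 98.5) < 3 * se
        assert not flagged


class TestMethylationSummary:
    def test_fully_methylated_sample(self):
        t = make_table("s", [("chr1", 10, 5, 0), ("chr1", 30, 2, 0)])
        rep = mh.methylation_summary(t)
        assert rep.global_5mC == 100.0
        assert rep.partial_fraction == 0.0
        assert rep.mean_depth == 3.5

    def test_partial_fraction_thresholds_strict(self):
        t = make_table("s", [
            ("chr1", 10, 1, 9),   # level 0.1 -> not partial (strict)
            ("chr1", 30, 2, 8),   # 0.2 -> partial
            ("chr1", 50, 9, 1),   # 0.9 -> not partial
        ])
        rep = mh.methylation_summary(t)
        assert rep.partial_fraction == pytest.approx(100 / 3)

    def test_deep_bulk_partial_fraction_near_truth(self):
        cfg = mh.SimulationConfig(
            n_chromosomes=1, chrom_length_bp=5_000_000, f_partial=0.0107,
            conv_fail=0.0, n_noncpg_sites=0, seed=33,
        )
        sites, _ = mh.build_synthetic_genome(cfg)
        bt = mh.simulate_bulk_truth(sites, cfg)
        bulk, _ = mh.simulate_calls(bt, "bulk", cfg, 34, "b")
        rep = mh.methylation_summary(bulk)
        # at depth ~30, nearly every Beta(5,5) partial site reads inside
        # (0.1, 0.9) and 0/1 sites never do (no conversion failure)
        assert rep.partial_fraction == pytest.approx(1.07, abs=0.25)

    def test_single_cell_shows_less_partial_than_bulk(self):
        # shallow cells rarely sample both alleles of a truly partial site, so
        # they report fewer intermediate levels than the deep bulk; conversion
        # failure is off to isolate that allelic-sampling mechanism from
        # threshold artifacts at depth ~2
        cfg = mh.SimulationConfig(
            n_chromosomes=1, chrom_length_bp=400_000, conv_fail=0.0, seed=35
        )
        ds = mh.simulate_dataset(cfg, n_cells=4)
        bulk_rep = mh.methylation_summary(ds.calls["bulk"])
        for i in (1, 2, 3, 4):
            cell_rep = mh.methylation_summary(ds.calls[f"hepatocyte_cell{i:02d}"])
            assert cell_rep.partial_fraction < bulk_rep.partial_fraction


class TestMergeCells:
    def test_single_cell_identity(self, small_dataset):
        c = small_dataset.calls["hepatocyte_cell01"]
        merged = mh.merge_cells([c], sample_id=c.sample_id)
        assert merged == c

    def test_counts_added_sitewise(self):
        a = make_table("a", [("chr1", 10, 3, 1)])
        b = make_table("b", [("chr1", 10, 0, 2), ("chr1", 50, 1, 0)])
        m = mh.merge_cells([a, b])
        assert m.df[["pos", "count_meth", "count_unmeth"]].values.tolist() == [
            [10, 3, 3], [50, 1, 0]
        ]

    def test_observation_conservation_and_commutativity(self, small_dataset):
        cells = [small_dataset.calls[f"hepatocyte_cell{i:02d}"] for i in (1, 2, 3)]
        m = mh.merge_cells(cells)
        assert int(m.depth.sum()) == sum(int(c.depth.sum()) for c in cells)
        m_rev = mh.merge_cells(cells[::-1])
        assert m.df.equals(m_rev.df)
        # associativity: (a+b)+c == a+(b+c)
        left = mh.merge_cells([mh.merge_cells(cells[:2]), cells[2]])
        right = mh.merge_cells([cells[0], mh.merge_cells(cells[1:])])
        assert left.df.equals(right.df)

    def test_merged_partial_fraction_exceeds_cells(self, small_dataset):
        cells = [small_dataset.calls[f"hepatocyte_cell{i:02d}"] for i in (1, 2, 3, 4)]
        merged = mh.merge_cells(cells)
        merged_partial = mh.methylation_summary(merged).partial_fraction
        for c in cells:
            assert mh.methylation_summary(c).partial_fraction < merged_partial


class TestMergedVsBulk:
    def test_pseudo_cell_merge_converges_to_bulk(self, small_dataset, small_windows):
        # pseudo-cells are resamples of the bulk itself, so their merge must
        # approach the bulk as cells accumulate
        ds = mh.simulate_dataset(small_dataset.config, n_cells=16)
        bulk = ds.calls["bulk"]
        pseudo = [
            mh.downsample_bulk_to_cell(
                bulk, ds.calls[f"hepatocyte_cell{i + 1:02d}"], seed=40 + i
            )
            for i in range(16)
        ]
        few = mh.merged_vs_bulk(mh.merge_cells(pseudo[:2]), bulk, small_windows, seed=0)
        many = mh.merged_vs_bulk(mh.merge_cells(pseudo), bulk, small_windows, seed=0)
        assert many.pearson_r > few.pearson_r
        assert many.mean_abs_diff < few.mean_abs_diff
        assert many.mean_abs_diff < 0.05

    def test_sample_cap_respected(self, small_dataset, small_windows):
        bulk = small_dataset.calls["bulk"]
        rep_all = mh.merged_vs_bulk(bulk, bulk, small_windows, n_sample=10**6)
        rep_cap = mh.merged_vs_bulk(bulk, bulk, small_windows, n_sample=50)
        assert rep_all.n_windows_used == rep_all.n_windows_available
        assert rep_cap.n_windows_used == 50


class TestPromoterPanel:
    @staticmethod
    def _sample(sid, level, rng, n_prom=20, depth=8):
        rows = []
        for j in range(n_prom):
            base = j * 10_000
            for k in range(4):
                m = rng.binomial(depth, level)
                rows.append(("chr1", base + 100 + 200 * k, m, depth - m))
        return make_table(sid, rows)

    @staticmethod
    def _panel(n_prom=20):
        return mh.FeatureMap(pd.DataFrame(
            {"chrom": "chr1", "start": [j * 10_000 for j in range(n_prom)],
             "end": [j * 10_000 + 1000 for j in range(n_prom)],
             "label": "promoter"}
        ))

    def test_hypomethylated_target_group_significant(self):
        rng = np.random.default_rng(50)
        tables = {}
        groups = {}
        for i in range(5):
            sid = f"hep{i}"
            tables[sid] = self._sample(sid, 0.05, rng)
            groups[sid] = "hepatocyte"
        for i in range(5):
            sid = f"fib{i}"
            tables[sid] = self._sample(sid, 0.8, rng)
            groups[sid] = "fibroblast"
        res = mh.promoter_panel_test(
            tables, groups, self._panel(), "hepatocyte", "fibroblast"
        )
        assert res.p_value < 0.001
        assert len(res.per_sample) == 10

    def test_identical_groups_null_p(self):
        rng = np.random.default_rng(51)
        tables = {}
        groups = {}
        for i in range(6):
            sid = f"s{i}"
            tables[sid] = self._sample(sid, 0.4, rng)
            groups[sid] = "a" if i < 3 else "b"
        res = mh.promoter_panel_test(tables, groups, self._panel(), "a", "b")
        assert 0.05 < res.p_value < 0.95

    def test_single_promoter_panel_warns(self):
        rng = np.random.default_rng(52)
        tables = {f"s{i}": self._sample(f"s{i}", 0.4, rng, n_prom=1)
                  for i in range(4)}
        groups = {f"s{i}": "a" if i < 2 else "b" for i in range(4)}
        with pytest.warns(UserWarning, match="low-powered"):
            mh.promoter_panel_test(tables, groups, self._panel(1), "a", "b")
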