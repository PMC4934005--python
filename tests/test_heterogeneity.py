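import numpy as np
import pandas as pd
import pytest

import methylhet as mh

from conftest import make_table, random_table


def naive_weighted_variance(pairs):
    num = den = 0.0
    for _, r in pairs.iterrows():
        w = r["n_obs_cell"]
        num += w * (r["m_cell"] - r["m_bulk"]) ** 2
        den += w
    return num / den


def pairs_frame(rows):
    """rows: (m_cell, m_bulk, n_obs_cell[, count_meth_cell])"""
    recs = []
    for i, r in enumerate(rows):
        m_cell, m_bulk, n_obs = r[:3]
        cm = r[3] if len(r) > 3 else int(round(m_cell * n_obs))
        recs.append(
            {"chrom": "chr1", "start": i * 3000, "end": (i + 1) * 3000,
             "m_cell": m_cell, "m_bulk": m_bulk, "n_obs_cell": n_obs,
             "count_meth_cell": cm, "m_bulk_shared": m_bulk}
        )
    return pd.DataFrame(recs)


class TestWeightedVariance:
    def test_identical_profiles_zero(self):
        p = pairs_frame([(0.3, 0.3, 10), (0.8, 0.8, 4)])
        assert mh.weighted_variance(p) == 0.0

    def test_hand_computed_two_windows(self):
        p = pairs_frame([(0.5, 0.3, 5), (0.2, 0.3, 10)])
        assert mh.weighted_variance(p) == pytest.approx(0.02)

    def test_single_window_weight_free(self):
        for w in (1, 7, 100):
            p = pairs_frame([(1.0, 0.5, w)])
            assert mh.weighted_variance(p) == pytest.approx(0.25)

    def test_matches_naive_loop_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 12)
            p = pairs_frame([
                (rng.random(), rng.random(), int(rng.integers(1, 40)))
                for _ in range(n)
            ])
            assert mh.weighted_variance(p) == pytest.approx(
                naive_weighted_variance(p), abs=1e-14
            )

    def test_zero_weight_rejected(self):
        p = pairs_frame([(0.5, 0.2, 0)])
        with pytest.raises(ValueError):
            mh.weighted_variance(p)


class TestDownsampleBulk:
    def test_equal_depth_site_copied_exactly(self):
        bulk = make_table("b", [("chr1", 10, 3, 2), ("chr1", 40, 0, 4)])
        cell = make_table("c", [("chr1", 10, 1, 4), ("chr1", 40, 4, 0)])
        pseudo = mh.downsample_bulk_to_cell(bulk, cell, seed=0)
        assert pseudo.df[["count_meth", "count_unmeth"]].values.tolist() == [
            [3, 2], [0, 4]
        ]

    def test_depth_profile_matches_cell(self, small_dataset):
        bulk = small_dataset.calls["bulk"]
        cell = small_dataset.calls["hepatocyte_cell01"]
        pseudo = mh.downsample_bulk_to_cell(bulk, cell, seed=1)
        joined = pd.merge(pseudo.df, cell.df, on=["chrom", "pos"],
                          suffixes=("_p", "_c"))
        assert len(joined) == pseudo.n_sites
        dp = joined["count_meth_p"] + joined["count_unmeth_p"]
        dc = joined["count_meth_c"] + joined["count_unmeth_c"]
        assert (dp == dc).all()  # bulk is deeper everywhere in this fixture

    def test_hypergeometric_spread_at_depth_one(self):
        # bulk 10/10 at one site; drawing 1 read gives 0 or 1 with equal
        # probability, so the mean squared deviation from 0.5 is 0.25
        bulk = make_table("b", [("chr1", 10, 10, 10)])
        cell = make_table("c", [("chr1", 10, 1, 0)])
        rng = np.random.default_rng(2)
        draws = [
            mh.downsample_bulk_to_cell(bulk, cell, rng).level.iloc[0]
            for _ in range(400)
        ]
        assert set(draws) <= {0.0, 1.0}
        msd = np.mean([(d - 0.5) ** 2 for d in draws])
        assert msd == pytest.approx(0.25, abs=0.02)

    def test_fixed_seed_reproducible(self, small_dataset):
        bulk = small_dataset.calls["bulk"]
        cell = small_dataset.calls["hepatocyte_cell02"]
        p1 = mh.downsample_bulk_to_cell(bulk, cell, seed=7)
        p2 = mh.downsample_bulk_to_cell(bulk, cell, seed=7)
        assert p1 == p2


class TestEstimateNoise:
    def test_cell_identical_to_bulk_zero_noise(self, small_dataset, small_windows):
        bulk = small_dataset.calls["bulk"]
        est = mh.estimate_noise(bulk, bulk, small_windows, n_rep=3, seed=0)
        assert est.noise_var == 0.0

    def test_noise_decreases_with_cell_depth(self):
        cfg = mh.SimulationConfig(
            n_chromosomes=1, chrom_length_bp=300_000, epsilon=0.0,
            conv_fail=0.0, f_partial=0.0, cell_site_coverage_prob=0.5, seed=3,
        )
        w = mh.build_windows({"chr1": 300_000})
        noises = []
        for depth in (1.0, 4.0, 16.0):
            ds = mh.simulate_dataset(cfg.with_(cell_depth_mean=depth), n_cells=1)
            est = mh.estimate_noise(
                ds.calls["bulk"], ds.calls["hepatocyte_cell01"], w, n_rep=5, seed=4
            )
            noises.append(est.noise_var)
        assert noises[0] > noises[1] > noises[2]

    def test_pseudo_cell_as_cell_corrects_to_zero(self, small_dataset, small_windows):
        # a pseudo-cell is distributed exactly like the downsampling
        # replicates, so raw variance minus estimated noise sits within the
        # replicate spread of zero
        bulk = small_dataset.calls["bulk"]
        profile = small_dataset.calls["hepatocyte_cell01"]
        pseudo = mh.downsample_bulk_to_cell(bulk, profile, seed=60)
        pairs = mh.paired_window_stats(pseudo, bulk, small_windows)
        raw = mh.weighted_variance(pairs)
        est = mh.estimate_noise(bulk, pseudo, small_windows, n_rep=20, seed=61)
        sd = est.replicates.std(ddof=1) * np.sqrt(1 + 1 / len(est.replicates))
        assert abs(raw - est.noise_var) < 3 * sd

    def test_replicates_retained(self, small_dataset, small_windows):
        est = mh.estimate_noise(
            small_dataset.calls["bulk"], small_dataset.calls["hepatocyte_cell01"],
            small_windows, n_rep=4, seed=5,
        )
        assert len(est.replicates) == 4
        assert est.noise_var == pytest.approx(est.replicates.mean())


class TestHeterogeneityProfile:
    def test_corrected_bounded_by_raw(self, small_dataset, small_windows):
        prof = mh.heterogeneity_profile(
            small_dataset.manifest, small_dataset.calls, small_windows,
            n_rep=5, seed=0,
        )
        assert (prof["error"] == "").all()
        assert (prof["corrected_var"] >= 0).all()
        assert (prof["corrected_var"] <= prof["raw_var"] + 1e-15).all()

    def test_more_epivariation_more_corrected_variance(self):
        cfg = mh.SimulationConfig(
            n_chromosomes=1, chrom_length_bp=400_000,
            cell_site_coverage_prob=0.5, conv_fail=0.0, seed=11,
        )
        w = mh.build_windows({"chr1": 400_000})
        out = {}
        for eps in (0.01, 0.1):
            ds = mh.simulate_dataset(cfg, n_cells=3, epsilon=eps)
            prof = mh.heterogeneity_profile(
                ds.manifest, ds.calls, w, n_rep=5, seed=12
            )
            out[eps] = prof["corrected_var"].mean()
        assert out[0.1] > out[0.01]


class TestPermutationTest:
    def test_identical_groups_large_p(self):
        p = mh.permutation_test_mean([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], tail="one")
        assert p >= 0.5

    def test_hand_enumerated_case(self):
        # C(4,2)=6 splits; only the observed split has stat >= 9 -> p = 1/6
        p = mh.permutation_test_mean([10.0, 11.0], [1.0, 2.0], tail="one")
        assert p == pytest.approx(1 / 6)

    def test_p_floor_monte_carlo(self):
        rng = np.random.default_rng(1)
        a = list(rng.normal(10, 0.1, size=10))
        b = list(rng.normal(0, 0.1, size=10))
        p = mh.permutation_test_mean(a, b, tail="one", n_perm=999, seed=2)
        assert p == pytest.approx(1 / 1000)

    def test_monte_carlo_converges_to_exhaustive(self):
        rng = np.random.default_rng(3)
        for na, nb in ((2, 2), (3, 3)):
            a = list(rng.normal(1, 1, size=na))
            b = list(rng.normal(0, 1, size=nb))
            for tail in ("one", "two"):
                exact = mh.permutation_test_mean(a, b, tail=tail,
                                                 method="exhaustive")
                mc = mh.permutation_test_mean(
                    a, b, tail=tail, n_perm=40_000, seed=4, method="monte-carlo"
                )
                se = np.sqrt(exact * (1 - exact) / 40_000)
                assert abs(mc - exact) < 3 * se + 1e-4

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mh.permutation_test_mean([1.0], [2.0, 3.0])


class TestCallDMWs:
    def test_identical_windows_no_dmws(self):
        p = pairs_frame([(0.5, 0.5, 20, 10), (0.9, 0.9, 10, 9)])
        res = mh.call_dmws(p)
        assert res.dmw_count == 0

    def test_extreme_divergence_called(self):
        # bulk window fully unmethylated (0/500 reads), cell 5/5 methylated:
        # binomial p-value vanishes and the effect size is 1.0
        p = pairs_frame([(1.0, 0.0, 5, 5)] + [(0.5, 0.5, 20, 10)] * 9)
        res = mh.call_dmws(p)
        assert res.dmw_count == 1
        assert bool(res.table["is_dmw"].iloc[0])

    def test_small_effect_never_called(self):
        # diff 0.2 < effect_min even with overwhelming counts
        p = pairs_frame([(0.7, 0.5, 1000, 700)])
        res = mh.call_dmws(p, effect_min=0.3)
        assert res.dmw_count == 0

    def test_frequency_monotone_in_thresholds(self, small_dataset, small_windows):
        ds = mh.simulate_dataset(
            small_dataset.config.with_(cell_site_coverage_prob=0.5, seed=13),
            n_cells=1, epsilon=0.25,
        )
        w = small_windows
        pairs = mh.paired_window_stats(
            ds.calls["hepatocyte_cell01"], ds.calls["bulk"], w
        )
        freqs_effect = [
            mh.call_dmws(pairs, effect_min=e).dmw_frequency for e in (0.1, 0.3, 0.5)
        ]
        assert freqs_effect == sorted(freqs_effect, reverse=True)
        freqs_alpha = [
            mh.call_dmws(pairs, alpha=a).dmw_frequency for a in (0.1, 0.05, 0.01)
        ]
        assert freqs_alpha == sorted(freqs_alpha, reverse=True)
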