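"""Gene aggregation, percentile outlier calls, method intersection and
top-ΔdAF variant selection."""
import numpy as np
import pandas as pd
import pytest

from coldscan.scan import (METHODS, aggregate_to_genes, call_outliers,
                           intersect_methods, percentile_ranks, top_variants)


def _genes(n, size=100):
    return pd.DataFrame({"chrom": "1", "start": np.arange(n) * size,
                         "end": (np.arange(n) + 1) * size,
                         "name": [f"g{i}" for i in range(n)]})


def _gene_stats(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "fst": rng.random(n), "pi_ratio": rng.random(n),
        "clr": rng.random(n), "ihh12_z": rng.random(n),
        "hka": rng.random(n),
    }, index=pd.Index([f"g{i}" for i in range(n)], name="gene"))


class TestAggregate:
    def _inputs(self):
        genes = _genes(5)
        windows = pd.DataFrame({
            "chrom": "1", "start": [0, 50, 100, 150, 380],
            "end": [100, 150, 200, 250, 450],
            "fst": [0.1, 0.4, 0.2, 0.05, 0.9],
            "log2_pi_ratio": [0.5, 1.0, -0.2, 2.0, 0.1],
        })
        grid = pd.DataFrame({"chrom": "1", "grid_pos": [50, 150, 250],
                             "clr": [3.0, 7.0, 1.0]})
        ihh = pd.DataFrame({"chrom": "1", "pos": [10, 120, 130, 410],
                            "z": [0.5, 2.5, -1.0, 4.0]})
        hka = pd.DataFrame({"unit": [f"g{i}" for i in range(5)],
                            "P": [10] * 5, "D": [100, 100, 100, 60, 100],
                            "usable": [True, True, True, False, True],
                            "signed_score": [0.1, 0.2, 0.3, 0.4, 0.5]})
        return genes, windows, grid, ihh, hka

    def test_gene_spanning_two_windows_takes_max(self):
        genes, windows, grid, ihh, hka = self._inputs()
        out = aggregate_to_genes(genes, windows, grid, ihh, hka)
        assert out.loc["g0", "fst"] == 0.4  # windows [0,100) and [50,150)
        assert out.loc["g0", "pi_ratio"] == 1.0

    def test_unusable_hka_unit_is_missing(self):
        genes, windows, grid, ihh, hka = self._inputs()
        out = aggregate_to_genes(genes, windows, grid, ihh, hka)
        assert np.isnan(out.loc["g3", "hka"])
        assert out.loc["g4", "hka"] == 0.5

    def test_full_hand_enumeration(self):
        genes, windows, grid, ihh, hka = self._inputs()
        out = aggregate_to_genes(genes, windows, grid, ihh, hka)
        # windows overlapping each gene (half-open):
        # g1 [100,200): w0? no. w1 [50,150) yes, w2 [100,200) yes, w3 [150,250) yes
        assert out.loc["g1", "fst"] == 0.4
        assert out.loc["g1", "pi_ratio"] == 2.0
        # grid points: g0 gets 50, g1 gets 150, g2 gets 250
        assert out.loc["g0", "clr"] == 3.0
        assert out.loc["g1", "clr"] == 7.0
        assert out.loc["g2", "clr"] == 1.0
        assert np.isnan(out.loc["g3", "clr"])
        # ihh z: g0 max(0.5), g1 max(2.5, -1.0), g4 4.0
        assert out.loc["g1", "ihh12_z"] == 2.5
        assert out.loc["g4", "ihh12_z"] == 4.0
        assert np.isnan(out.loc["g2", "ihh12_z"])


class TestOutliers:
    def test_joint_top_ten_of_two_hundred(self):
        n = 200
        rng = np.random.default_rng(1)
        gs = _gene_stats(n, seed=1)
        flags = call_outliers(gs, q_pair=0.05)
        top_fst = set(gs["fst"].nlargest(10).index)
        top_ratio = set(gs["pi_ratio"].nlargest(10).index)
        want = top_fst & top_ratio
        got = set(flags.index[flags["fst_pi"]])
        assert got == want

    def test_identical_values_give_no_outliers(self):
        gs = _gene_stats(50)
        for c in gs.columns:
            gs[c] = 1.0
        flags = call_outliers(gs)
        for m in METHODS:
            assert not flags[m].any()

    def test_single_stat_flag_count_matches_quantile(self):
        for seed in range(10):
            gs = _gene_stats(1000, seed=seed)
            flags = call_outliers(gs, q_site=0.01)
            assert abs(int(flags["ihh12"].sum()) - 10) <= 1
            assert abs(int(flags["hka"].sum()) - 10) <= 1

    def test_inf_ranks_top(self):
        gs = _gene_stats(100, seed=2)
        gs.loc["g7", "pi_ratio"] = np.inf
        gs.loc["g7", "fst"] = gs["fst"].max() + 1
        flags = call_outliers(gs, q_pair=0.05)
        assert flags.loc["g7", "fst_pi"]

    def test_nan_genes_excluded_from_percentiles(self):
        v = np.array([np.nan, 1.0, 2.0, 3.0])
        pct = percentile_ranks(v)
        assert np.isnan(pct[0])
        assert pct[3] == 1.0

    def test_candidates_monotone_in_q(self):
        gs = _gene_stats(300, seed=3)
        lo = intersect_methods(call_outliers(gs, q_pair=0.02, q_site=0.005))
        hi = intersect_methods(call_outliers(gs, q_pair=0.10, q_site=0.05))
        assert set(lo.index[lo["candidate"]]) <= set(hi.index[hi["candidate"]])

    def test_ranksum_mode_runs(self):
        gs = _gene_stats(100, seed=4)
        flags = call_outliers(gs, pair_mode="ranksum")
        assert flags["fst_pi"].sum() >= 1

    def test_label_permutation_equivariance(self):
        gs = _gene_stats(80, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(gs))
        flags = call_outliers(gs)
        flags_p = call_outliers(gs.iloc[perm])
        for m in METHODS:
            assert flags[m].sort_index().equals(flags_p[m].sort_index())


class TestIntersect:
    def _flags(self, support):
        idx = pd.Index([f"g{i}" for i in range(len(support))], name="gene")
        df = pd.DataFrame(False, index=idx, columns=list(METHODS))
        for i, methods in enumerate(support):
            for m in methods:
                df.loc[f"g{i}", m] = True
        return df

    def test_three_methods_candidate_not_strict(self):
        out = intersect_methods(self._flags([("fst_pi", "ihh12", "hka")]))
        assert out["candidate"].iloc[0] and not out["strict"].iloc[0]

    def test_two_methods_not_candidate(self):
        out = intersect_methods(self._flags([("fst_pi", "ihh12")]))
        assert not out["candidate"].iloc[0]

    def test_strict_subset_of_candidate(self):
        rng = np.random.default_rng(6)
        gs = _gene_stats(400, seed=6)
        out = intersect_methods(call_outliers(gs))
        assert set(out.index[out["strict"]]) <= set(out.index[out["candidate"]])

    def test_independent_null_rates_yield_no_strict_genes(self):
        # E[#4-method genes] = 20000 * .05 * .05 * .01 * .01 = 0.005
        n = 20_000
        idx = pd.Index([f"g{i}" for i in range(n)])
        for seed in range(10):
            rng = np.random.default_rng(seed)
            flags = pd.DataFrame({
                "fst_pi": rng.random(n) < 0.05,
                "xpclr_pi": rng.random(n) < 0.05,
                "ihh12": rng.random(n) < 0.01,
                "hka": rng.random(n) < 0.01,
            }, index=idx)
            out = intersect_methods(flags)
            assert int(out["strict"].sum()) == 0


class TestTopVariants:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "id",
                                           "effect_class", "polarized",
                                           "delta_daf"])

    def _calls(self, genes_support):
        idx = pd.Index(list(genes_support), name="gene")
        return pd.DataFrame({"n_support": list(genes_support.values())},
                            index=idx)

    def test_regulatory_beats_lower_daf(self):
        genes = _genes(1, size=1000)
        sites = self._sites([("1", 10, "a", "regulatory", True, 0.9),
                             ("1", 20, "b", "other", True, 0.7)])
        lead = top_variants(sites, genes, self._calls({"g0": 4}))
        assert lead["regulatory"]["pos"] == 10
        assert lead["exonic"] is None

    def test_ties_reported_smaller_coordinate_leads(self):
        genes = _genes(1, size=1000)
        sites = self._sites([("1", 50, "a", "missense", True, 0.8),
                             ("1", 10, "b", "missense", True, 0.8)])
        lead = top_variants(sites, genes, self._calls({"g0": 4}))
        assert lead["exonic"]["pos"] == 10
        assert lead["exonic"]["ties"] == [10, 50]

    def test_min_support_restricts_genes(self):
        genes = _genes(2, size=100)
        sites = self._sites([("1", 50, "a", "regulatory", True, 0.9),
                             ("1", 150, "b", "regulatory", True, 0.95)])
        calls = self._calls({"g0": 4, "g1": 3})
        strict = top_variants(sites, genes, calls, min_support=4)
        loose = top_variants(sites, genes, calls, min_support=3)
        assert strict["regulatory"]["pos"] == 50
        assert loose["regulatory"]["pos"] == 150

    def test_unpolarized_sites_excluded(self):
        genes = _genes(1, size=1000)
        sites = self._sites([("1", 10, "a", "regulatory", False, 0.99),
                             ("1", 20, "b", "regulatory", True, 0.5)])
        lead = top_variants(sites, genes, self._calls({"g0": 4}))
        assert lead["regulatory"]["pos"] == 20

    def test_sweep_truth_site_is_regulatory_leader(self, sweep_sim_complete):
        from coldscan import pipeline
        sim = sweep_sim_complete
        rc = pipeline.RunConfig(seed=11, run_ibstree=False,
                                min_support_leaders=3)
        res = pipeline.run_scan(sim.hm, sim.vt, sim.popmap, sim.genes, rc)
        lead = res["summary"]["leaders"]
        assert lead["regulatory"]["pos"] == sim.truth["sweep_pos_regulatory"]
        assert lead["exonic"]["pos"] == sim.truth["sweep_pos_missense"]
        assert lead["regulatory"]["delta_daf"] == 1.0
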