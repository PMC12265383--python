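"""EHH / EHH12 / iHH12 against string-based partition oracles and the sweep
fixture's qualitative decay contrast."""
import numpy as np
import pytest

from _util import ehh_curve_oracle, hm_from_rows, ihh12_oracle, vt_for
from coldscan import popio
from coldscan.haplostats import (EhhCurve, ehh, ehh12_curve, ihh12_scan,
                                 ihh12_site, standardize_ihh12)
from coldscan.popio import MISSING


def _random_fixture(seed, H=10, V=20, missing=0.0):
    rng = np.random.default_rng(seed)
    if missing:
        a = rng.choice([0, 1, MISSING], size=(H, V),
                       p=[(1 - missing) / 2, (1 - missing) / 2, missing])
    else:
        a = rng.integers(0, 2, size=(H, V))
    a = a.astype(np.int8)
    core = V // 2
    # make the core column biallelic and missing-free
    a[:, core] = (np.arange(H) % 2)
    pos = np.sort(rng.choice(np.arange(1, 50_000), size=V, replace=False))
    return hm_from_rows(a), vt_for(pos), core


class TestEhh:
    def test_core_value_is_one(self):
        hm, vt, core = _random_fixture(0)
        c = ehh(hm, vt, core, allele=1)
        assert c.ehh[np.searchsorted(c.offsets, 0)] == 1.0

    def test_shared_haplotype_stays_one_to_contig_end(self):
        a = np.zeros((6, 8), dtype=np.int8)
        a[:, 4] = 1  # all carry the core allele on an identical background
        hm = hm_from_rows(a)
        c = ehh(hm, vt_for(range(1, 9)), 4, allele=1)
        assert np.all(c.ehh == 1.0)
        assert c.trunc_left == c.trunc_right == "contig_end"

    def test_fewer_than_two_carriers_raises(self):
        a = np.zeros((4, 3), dtype=np.int8)
        a[0, 1] = 1
        hm = hm_from_rows(a)
        with pytest.raises(ValueError, match="carriers"):
            ehh(hm, vt_for([1, 2, 3]), 1, allele=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_partition_oracle(self, seed):
        hm, vt, core = _random_fixture(seed)
        pos = vt["pos"].to_numpy()
        for allele in (0, 1):
            got = ehh(hm, vt, core, allele, cutoff=0.0)
            carriers = np.flatnonzero(hm.alleles[:, core] == allele)
            offs, vals = ehh_curve_oracle(hm.alleles, pos, core, carriers,
                                          cutoff=0.0, max_gap=200_000,
                                          pooled=False)
            assert np.array_equal(got.offsets, offs)
            assert np.allclose(got.ehh, vals, atol=1e-12)

    def test_matches_oracle_with_missing_data(self):
        hm, vt, core = _random_fixture(9, H=12, V=25, missing=0.15)
        got = ehh(hm, vt, core, 1, cutoff=0.0)
        carriers = np.flatnonzero(hm.alleles[:, core] == 1)
        offs, vals = ehh_curve_oracle(hm.alleles, vt["pos"].to_numpy(), core,
                                      carriers, 0.0, 200_000, pooled=False)
        assert np.array_equal(got.offsets, offs)
        assert np.allclose(got.ehh, vals, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_nonincreasing_without_missing(self, seed):
        hm, vt, core = _random_fixture(seed + 20, H=12, V=30)
        c = ehh(hm, vt, core, 1, cutoff=0.0)
        i0 = int(np.searchsorted(c.offsets, 0))
        right = c.ehh[i0:]
        left = c.ehh[:i0 + 1][::-1]
        assert np.all(np.diff(right) <= 1e-12)
        assert np.all(np.diff(left) <= 1e-12)

    def test_resolves_derived_and_ancestral_labels(self):
        hm, vt, core = _random_fixture(1)
        vt.loc[core, "ancestral_state"] = "alt"  # derived allele is REF
        d = ehh(hm, vt, core, "derived")
        r = ehh(hm, vt, core, 0)
        assert np.array_equal(d.ehh, r.ehh)


class TestIhh12:
    def test_rectangle_integral(self):
        # biallelic core mid-contig, identical flanks: EHH12 = 1 both sides
        a = np.zeros((4, 3), dtype=np.int8)
        a[:2, 1] = 1
        hm = hm_from_rows(a)
        vt = vt_for([1, 50_001, 100_001])
        assert ihh12_site(hm, vt, 1) == pytest.approx(100_000.0)

    def test_monomorphic_core_rejected(self):
        a = np.zeros((4, 3), dtype=np.int8)
        hm = hm_from_rows(a)
        with pytest.raises(ValueError, match="biallelic"):
            ihh12_site(hm, vt_for([1, 2, 3]), 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_integral(self, seed):
        hm, vt, core = _random_fixture(seed + 40)
        got = ihh12_site(hm, vt, core, cutoff=0.05)
        want = ihh12_oracle(hm.alleles, vt["pos"].to_numpy(), core,
                            np.arange(hm.n_haplotypes), 0.05, 200_000)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_pooling_dominates_unpooled_homozygosity(self, seed):
        # pooling the top two classes can only merge classes, so EHH12 is
        # bounded below by the unpooled all-haplotype homozygosity of the
        # identical partition (string-refinement oracle)
        hm, vt, core = _random_fixture(seed + 60)
        pooled = ehh12_curve(hm, vt, core, cutoff=0.0)
        offs, unpooled = ehh_curve_oracle(
            hm.alleles, vt["pos"].to_numpy(), core,
            np.arange(hm.n_haplotypes), cutoff=0.0, max_gap=200_000,
            pooled=False, init_core=True)
        assert np.array_equal(pooled.offsets, offs)
        assert np.all(pooled.ehh >= unpooled - 1e-12)

    def test_invariant_to_row_order_and_label_swap(self):
        hm, vt, core = _random_fixture(3)
        base = ihh12_site(hm, vt, core)
        rng = np.random.default_rng(0)
        assert ihh12_site(hm_from_rows(hm.alleles[rng.permutation(10)]), vt,
                          core) == pytest.approx(base)
        assert ihh12_site(hm_from_rows(1 - hm.alleles), vt,
                          core) == pytest.approx(base)

    def test_max_gap_truncates(self):
        a = np.zeros((4, 3), dtype=np.int8)
        a[:2, 1] = 1
        hm = hm_from_rows(a)
        vt = vt_for([1, 50_001, 400_001])  # right gap 350 kb > 200 kb
        c = ehh12_curve(hm, vt, 1)
        assert c.trunc_right == "max_gap"
        assert ihh12_site(hm, vt, 1) == pytest.approx(50_000.0)


class TestStandardize:
    def _table(self, v):
        import pandas as pd
        return pd.DataFrame({"chrom": "1", "pos": np.arange(len(v)) + 1,
                             "ihh12": v, "n_hap": 10})

    def test_constant_vector_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = standardize_ihh12(self._table(np.full(60, 3.0)))
        assert np.all(out["z"] == 0)

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        out = standardize_ihh12(self._table(rng.gamma(2, 1000, 500)))
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_binned_mode_centers_each_bin(self):
        rng = np.random.default_rng(1)
        v = rng.gamma(2, 1000, 400)
        freq = rng.random(400)
        out = standardize_ihh12(self._table(v), freq=freq, n_bins=10)
        edges = np.linspace(0, 1, 11)
        for b in range(10):
            m = (freq >= edges[b]) & (freq < edges[b + 1])
            if m.sum() >= 2:
                assert out["z"][m].mean() == pytest.approx(0.0, abs=1e-9)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            standardize_ihh12(self._table(np.ones(10)))


def test_sweep_derived_ehh_outlives_ancestral(sweep_sim_complete):
    """The planted derived allele keeps haplotype homozygosity over a longer
    range than the ancestral allele (the EHH 'hat' asymmetry)."""
    sim = sweep_sim_complete
    vt = popio.polarize(sim.hm, sim.vt, sim.popmap)
    j = int(np.flatnonzero(vt["pos"].to_numpy()
                           == sim.truth["sweep_pos_regulatory"])[0])
    rows = sim.hm.rows_for(sim.popmap.samples(role="focal")
                           + sim.popmap.samples(role="reference"))
    der = ehh(sim.hm, vt, j, "derived", rows)
    anc = ehh(sim.hm, vt, j, "ancestral", rows)
    assert der.area() > anc.area()


def test_sweep_ihh12_elevated_inside_interval(sweep_sim):
    sim = sweep_sim  # f = 0.9 keeps polymorphic cores inside the sweep
    hm, vt, _ = popio.apply_filters(sim.hm, sim.vt, sim.popmap)
    tab = ihh12_scan(hm, vt, sim.popmap)
    pos = tab["pos"].to_numpy()
    inside = (pos >= sim.truth["sweep_start"]) & (pos < sim.truth["sweep_end"])
    assert inside.sum() > 10
    assert tab["ihh12"][inside].mean() > 2 * tab["ihh12"].median()
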