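"""Synthetic cold/warm/outgroup haplotype data with an injectable hard sweep.

The generator emulates the sampling design of a two-population cold-adaptation
scan: a focal "cold" population, a reference "warm" population and an
outgroup panel of sister species, on a single test contig.

Neutral background
------------------
Polymorphic biallelic sites are placed uniformly on ``[0, L)``.  Each site
draws an ancestral derived-allele frequency ``p ~ U(0.05, 0.95)``; focal and
reference population frequencies are independent Balding-Nichols draws
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around it, with ``F = fst_background``, and
haplotype alleles are Bernoulli in each population.  The site count is chosen
so expected per-bp heterozygosity within each pig population equals
``theta_site``.  The outgroup is fixed for the ancestral allele at every
pig-polymorphic site; additional outgroup-divergent sites (pigs fixed
ancestral, outgroup fixed for the other allele) arise at rate ``d_og`` per bp.

Hard sweep
----------
The sweep is injected by haplotype replacement: a donor focal haplotype is
copied over a fraction ``f`` of focal haplotypes across the sweep interval,
and two new linked derived variants carried by exactly the swept haplotypes
are added (a regulatory one at ``sweep_center`` and a missense one slightly
downstream) so the top-variant ranking can be validated for both effect
classes.  This produces the four signatures the scan consumes: reduced focal
diversity, elevated Fst, extended haplotype homozygosity and a focal derived
frequency of ``round(f * 2N) / 2N`` at the truth sites.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .popio import HaplotypeMatrix, PopulationMap, _new_variant_table

CHROM = "1"
# E[2p(1-p)] for p ~ U(0.05, 0.95): calibrates the segregating-site count
# so per-bp heterozygosity matches theta_site.
_HET_UNIFORM = 0.365
_P_LO, _P_HI = 0.05, 0.95
# background effect-class mix (regulatory/missense/synonymous/other)
EFFECT_PROBS = {"regulatory": 0.10, "missense": 0.05, "synonymous": 0.05, "other": 0.80}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    L: int = 2_000_000
    n_focal: int = 15
    n_reference: int = 21
    n_outgroup: int = 15
    theta_site: float = 1e-3
    d_og: float = 5e-3
    fst_background: float = 0.05
    sweep_on: bool = False
    sweep_center: int = 1_100_000
    sweep_width: int = 200_000
    sweep_fraction: float = 0.9
    sweep_missense_offset: int = 1_000
    n_genes: int = 10

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("zero-length sequence")
        if min(self.n_focal, self.n_reference, self.n_outgroup) < 2:
            raise ValueError("sample counts must be >= 2")
        if not 0.0 <= self.sweep_fraction <= 1.0:
            raise ValueError("sweep_fraction must be in [0, 1]")
        if not 0.0 <= self.theta_site < 1.0 or not 0.0 < self.d_og < 1.0:
            raise ValueError("require 0 <= theta_site < 1 and 0 < d_og < 1")
        if self.theta_site >= self.d_og:
            raise ValueError("require theta_site < d_og")
        if not 0.0 <= self.fst_background < 1.0:
            raise ValueError("fst_background must be in [0, 1)")
        if self.sweep_on:
            lo, hi = self.sweep_interval
            if lo < 0 or hi > self.L:
                raise ValueError("sweep interval must lie within [0, L)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @property
    def sweep_interval(self) -> tuple[int, int]:
        half = self.sweep_width // 2
        return self.sweep_center - half, self.sweep_center + half


@dataclass
class SimOutput:
    hm: HaplotypeMatrix
    vt: pd.DataFrame
    popmap: PopulationMap
    genes: pd.DataFrame
    truth: dict | None
    config: SimConfig


def _gene_tiles(L: int, n_genes: int) -> pd.DataFrame:
    bounds = np.round(np.linspace(0, L, n_genes + 1)).astype(np.int64)
    return pd.DataFrame({
        "chrom": CHROM,
        "start": bounds[:-1],
        "end": bounds[1:],
        "name": [f"gene_{i + 1:03d}" for i in range(n_genes)],
    })


def _popmap(cfg: SimConfig) -> PopulationMap:
    samples = {}
    for i in range(cfg.n_focal):
        samples[f"cold_{i + 1:02d}"] = "cold"
    for i in range(cfg.n_reference):
        samples[f"warm_{i + 1:02d}"] = "warm"
    for i in range(cfg.n_outgroup):
        samples[f"og_{i + 1:02d}"] = "outgroup"
    roles = {"cold": "focal", "warm": "reference", "outgroup": "outgroup"}
    return PopulationMap(samples, roles)


def simulate_neutral(config: SimConfig) -> SimOutput:
    """Neutral Balding-Nichols background plus outgroup divergence."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    F = cfg.fst_background

    if cfg.theta_site > 0:
        n_poly = int(round(cfg.theta_site * cfg.L / (_HET_UNIFORM * (1.0 - F))))
    else:
        n_poly = 0
    n_div = int(rng.binomial(cfg.L, cfg.d_og))
    total = n_poly + n_div
    positions = np.sort(rng.choice(cfg.L, size=total, replace=False))
    # interleave site types uniformly over the drawn positions
    is_poly = np.zeros(total, dtype=bool)
    is_poly[rng.choice(total, size=n_poly, replace=False)] = True

    nf, nr, no = 2 * cfg.n_focal, 2 * cfg.n_reference, 2 * cfg.n_outgroup
    H = nf + nr + no
    alleles = np.zeros((H, total), dtype=np.int8)

    # polymorphic sites: derived-allele draws per population, ascertained to
    # segregate within each pig population sample (a joint-called SNP panel
    # contains no site invisible in one of the panels; this also guarantees
    # that no background site can mimic the planted sweep variant's
    # fixed-in-focal / absent-in-reference configuration)
    def _draw(m: int) -> tuple[np.ndarray, np.ndarray]:
        p = rng.uniform(_P_LO, _P_HI, size=m)
        if F > 0:
            a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
            pf = rng.beta(a, b)
            pr = rng.beta(a, b)
        else:
            pf = pr = p
        hf = (rng.random((nf, m)) < pf).astype(np.int8)
        hr = (rng.random((nr, m)) < pr).astype(np.int8)
        return hf, hr

    hap_f = np.zeros((nf, n_poly), dtype=np.int8)
    hap_r = np.zeros((nr, n_poly), dtype=np.int8)
    todo = np.arange(n_poly)
    while todo.size:
        hf, hr = _draw(todo.size)
        seg = ((hf.sum(axis=0) % nf != 0) & (hr.sum(axis=0) % nr != 0))
        keep = np.flatnonzero(seg)
        hap_f[:, todo[keep]] = hf[:, keep]
        hap_r[:, todo[keep]] = hr[:, keep]
        todo = todo[~seg]
    poly_idx = np.flatnonzero(is_poly)
    alleles[:nf, poly_idx] = hap_f
    alleles[nf:nf + nr, poly_idx] = hap_r
    # outgroup stays 0 = ancestral at pig-polymorphic sites

    # divergent sites: pigs fixed ancestral (0), outgroup fixed derived (1)
    div_idx = np.flatnonzero(~is_poly)
    alleles[nf + nr:, div_idx] = 1

    # randomize which of REF/ALT is ancestral (allele codes: 0=REF, 1=ALT)
    anc_is_ref = rng.random(total) < 0.5
    flip = ~anc_is_ref
    alleles[:, flip] = 1 - alleles[:, flip]

    ref_base = rng.integers(0, 4, size=total)
    alt_base = (ref_base + rng.integers(1, 4, size=total)) % 4
    effects = rng.choice(list(EFFECT_PROBS), size=total, p=list(EFFECT_PROBS.values()))

    vt = _new_variant_table(total)
    vt["chrom"] = CHROM
    vt["pos"] = positions + 1  # 1-based VCF coordinate
    vt["ref"] = _BASES[ref_base]
    vt["alt"] = _BASES[alt_base]
    vt["effect_class"] = effects

    hm = HaplotypeMatrix(alleles, list(_popmap(cfg).sample_group), phased=True)
    return SimOutput(hm, vt, _popmap(cfg), _gene_tiles(cfg.L, cfg.n_genes),
                     truth=None, config=cfg)


def inject_sweep(neutral: SimOutput, config: SimConfig) -> SimOutput:
    """Replace a fraction f of focal haplotypes by a donor within the sweep
    interval and add two new derived truth variants carried by the swept set."""
    cfg = config
    if not cfg.sweep_on:
        raise ValueError("inject_sweep requires sweep_on=True")
    nf = 2 * cfg.n_focal
    n_swept = int(round(cfg.sweep_fraction * nf))
    if n_swept < 2:
        raise ValueError("sweep class must contain >= 2 haplotypes "
                         f"(f * 2 * n_focal = {cfg.sweep_fraction * nf:.2f})")
    rng = np.random.default_rng([cfg.seed, 2])
    start, end = cfg.sweep_interval

    alleles = neutral.hm.alleles.copy()
    vt = neutral.vt.copy()
    pos0 = vt["pos"].to_numpy() - 1
    in_interval = (pos0 >= start) & (pos0 < end)
    swept = np.sort(rng.choice(nf, size=n_swept, replace=False))
    donor = int(swept[0])
    cols = np.flatnonzero(in_interval)
    alleles[np.ix_(swept, cols)] = alleles[donor, cols]

    # two new linked derived variants carried by exactly the swept haplotypes
    taken = set(pos0.tolist())

    def _free(p0: int) -> int:
        while p0 in taken:
            p0 += 1
        taken.add(p0)
        return p0

    new_sites = [
        (_free(cfg.sweep_center), "regulatory"),
        (_free(cfg.sweep_center + cfg.sweep_missense_offset), "missense"),
    ]
    extra = _new_variant_table(len(new_sites))
    cols_new = np.zeros((alleles.shape[0], len(new_sites)), dtype=np.int8)
    for j, (p0, eff) in enumerate(new_sites):
        base = rng.integers(0, 4)
        extra.loc[j, ["chrom", "pos", "ref", "alt", "effect_class"]] = (
            CHROM, p0 + 1, _BASES[base], _BASES[(base + 1) % 4], eff)
        extra.loc[j, "id"] = f"sweep_{eff}"
        cols_new[swept, j] = 1
    if not (start <= new_sites[1][0] < end):
        raise ValueError("missense truth site falls outside the sweep interval")

    alleles = np.concatenate([alleles, cols_new], axis=1)
    vt = pd.concat([vt, extra], ignore_index=True)
    order = np.argsort(vt["pos"].to_numpy(), kind="stable")
    vt = vt.iloc[order].reset_index(drop=True)
    alleles = alleles[:, order]

    genes = neutral.genes
    hit = genes[(genes.start <= cfg.sweep_center) & (cfg.sweep_center < genes.end)]
    truth = {
        "sweep_start": start,
        "sweep_end": end,
        "sweep_center": cfg.sweep_center,
        "sweep_fraction": cfg.sweep_fraction,
        "sweep_fraction_realized": n_swept / nf,
        "sweep_pos_regulatory": new_sites[0][0] + 1,
        "sweep_pos_missense": new_sites[1][0] + 1,
        "derived_allele": "alt",
        "sweep_gene": hit["name"].iloc[0] if len(hit) else None,
    }
    hm = HaplotypeMatrix(alleles, list(neutral.hm.sample_ids), phased=True)
    return SimOutput(hm, vt, neutral.popmap, genes, truth, cfg)


def simulate(config: SimConfig) -> SimOutput:
    """Neutral simulation, plus sweep injection when ``sweep_on`` is set."""
    neutral = simulate_neutral(dataclasses.replace(config, sweep_on=False))
    if config.sweep_on:
        return inject_sweep(neutral, config)
    return neutral


# ---------------------------------------------------------------------------
# file output


def write_vcf(sim: SimOutput, path: str | Path) -> None:
    hm, vt = sim.hm, sim.vt
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={CHROM},length={sim.config.L}>\n")
        fh.write('##INFO=<ID=EFFECT,Number=1,Type=String,'
                 'Description="Variant effect class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hm.sample_ids) + "\n")
        a = hm.alleles
        for j in range(hm.n_sites):
            row = vt.iloc[j]
            gts = "\t".join(
                f"{a[2 * i, j]}|{a[2 * i + 1, j]}".replace("-1", ".")
                for i in range(hm.n_samples))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\tEFFECT={row.effect_class}\tGT\t{gts}\n")


def write_outputs(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write VCF, popmap TSV, gene BED and truth JSON into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "sim.vcf",
        "popmap": out / "popmap.tsv",
        "genes": out / "genes.bed",
        "truth": out / "truth.json",
    }
    write_vcf(sim, paths["vcf"])
    sim.popmap.to_tsv(paths["popmap"])
    sim.genes[["chrom", "start", "end", "name"]].to_csv(
        paths["genes"], sep="\t", header=False, index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth if sim.truth is not None else {}, fh, indent=2)
        fh.write("\n")
    return paths
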