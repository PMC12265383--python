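"""Pipeline orchestration: simulate/load -> filter & polarize -> the four
scans -> candidate calling -> report.

The in-memory core is :func:`run_scan`; :func:`run_all` wraps it with file
I/O, a YAML-config provenance record and a machine-readable summary JSON.
Every output table carries a header comment with the config hash and seed,
and re-running an identical config reproduces all outputs byte-identically.

One structural choice worth knowing about: the MAF filter is applied for the
frequency- and haplotype-based statistics only.  HKA polymorphism/divergence
counting runs on the missingness-filtered (but not MAF-filtered) site set,
because fixed interspecies differences are monomorphic within the pig
populations and a within-pig MAF filter would delete the divergence signal
wholesale.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import haplostats, hka, ibstree, popio, scan, sitestats, synthdata, xpclr

log = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4


@dataclass
class RunConfig:
    vcf: str | None = None
    popmap: str | None = None
    genes: str | None = None
    outdir: str = "coldscan_out"
    seed: int = 0
    # filtering / polarization
    maf: float = 0.05
    max_missing: float = 0.2
    min_outgroup: int = 2
    # windows
    window_size: int = 50_000
    window_step: int = 25_000
    contig_length: int | None = None
    # xpclr
    xpclr_grid_spacing: int = 10_000
    xpclr_window_radius: int = 250_000
    xpclr_max_snps: int = 200
    rho: float = 1e-8
    # haplostats
    ehh_cutoff: float = 0.05
    ehh_max_gap: int = 200_000
    # hka
    divergence_min: int = 60
    # calling
    q_pair: float = 0.05
    q_site: float = 0.01
    pair_mode: str = "joint"
    min_support_leaders: int = 4
    # stage toggles
    run_ibstree: bool = True
    thin_count: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded: the same scan on
        the same data written elsewhere is the same scan)."""
        d = dataclasses.asdict(self)
        for key in ("vcf", "popmap", "genes", "outdir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_scan(hm: popio.HaplotypeMatrix, vt: pd.DataFrame,
             popmap: popio.PopulationMap, genes: pd.DataFrame,
             cfg: RunConfig) -> dict:
    """Run filtering, the four statistics and candidate calling in memory.

    Returns a dict of stage tables plus a JSON-serializable ``summary``.
    """
    popmap.require_scan_layout()

    # missingness-only set (HKA substrate), then the fully filtered set
    hm_m, vt_m, rep_missing = popio.apply_filters(
        hm, vt, popmap, maf=0.0, max_missing=cfg.max_missing)
    hm_f, vt_f, rep_full = popio.apply_filters(
        hm_m, vt_m, popmap, maf=cfg.maf, max_missing=cfg.max_missing)
    vt_m = popio.polarize(hm_m, vt_m, popmap, cfg.min_outgroup)
    vt_f = popio.polarize(hm_f, vt_f, popmap, cfg.min_outgroup)

    contig_length = cfg.contig_length
    if contig_length is None:
        contig_length = int(max(genes["end"].max(), vt["pos"].max()))
    chroms = {str(genes["chrom"].iloc[0]): contig_length}
    windows = popio.make_windows(chroms, cfg.window_size, cfg.window_step)

    wstats = sitestats.window_stats(hm_f, vt_f, popmap, windows)
    sites = sitestats.site_table(hm_f, vt_f, popmap)

    grid = xpclr.xpclr_scan(
        hm_f, vt_f, popmap,
        rho=cfg.rho, grid_spacing=cfg.xpclr_grid_spacing,
        window_radius=cfg.xpclr_window_radius, max_snps=cfg.xpclr_max_snps,
        contig_length=contig_length)

    ihh = haplostats.ihh12_scan(hm_f, vt_f, popmap,
                                cutoff=cfg.ehh_cutoff, max_gap=cfg.ehh_max_gap)
    ihh = haplostats.standardize_ihh12(ihh)

    pd_counts = hka.count_pd(hm_m, vt_m, popmap, genes, cfg.min_outgroup)
    hka_records = hka.hka_test(pd_counts, cfg.divergence_min)

    gene_stats = scan.aggregate_to_genes(genes, wstats, grid, ihh, hka_records)
    flags = scan.call_outliers(gene_stats, cfg.q_pair, cfg.q_site, cfg.pair_mode)
    calls = scan.intersect_methods(flags)
    leaders = scan.top_variants(sites, genes, calls,
                                min_support=cfg.min_support_leaders)

    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "n_sites_input": int(hm.n_sites),
        "n_sites_missing_filtered": int(hm_m.n_sites),
        "n_sites_maf_filtered": int(hm_f.n_sites),
        "n_genes": int(len(genes)),
        "candidate_genes": sorted(calls.index[calls["candidate"]].tolist()),
        "strict_genes": sorted(calls.index[calls["strict"]].tolist()),
        "leaders": leaders,
    }
    result = {
        "windows": wstats, "sites": sites, "xpclr": grid, "ihh12": ihh,
        "hka": hka_records, "gene_stats": flags, "calls": calls,
        "summary": summary,
        "filtered": (hm_f, vt_f), "missing_filtered": (hm_m, vt_m),
    }
    if cfg.run_ibstree:
        idx = ibstree.thin_variants(vt_f, min(cfg.thin_count, len(vt_f)), cfg.seed)
        dos = ibstree.genotype_dosage(hm_f.take_sites(idx))
        dist = ibstree.ibs_distance(dos)
        result["ibs_dist"] = (dist, hm_f.sample_ids)
        result["newick"] = ibstree.nj_tree(dist, hm_f.sample_ids)
        summary["newick"] = result["newick"]
    return result


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# coldscan config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")


def run_all(cfg: RunConfig) -> dict:
    """File-level pipeline: read inputs, run the scan, write all outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not (cfg.vcf and cfg.popmap and cfg.genes):
        raise ValueError("run_all needs vcf, popmap and genes paths")
    for p in (cfg.vcf, cfg.popmap, cfg.genes):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    popmap = popio.PopulationMap.from_tsv(cfg.popmap)
    hm, vt, _ = popio.read_vcf(cfg.vcf, popmap)
    genes = popio.read_bed(cfg.genes)

    stage = "scan"
    try:
        result = run_scan(hm, vt, popmap, genes, cfg)
        stage = "write"
        _write_table(result["windows"], outdir / "windows.tsv", cfg)
        _write_table(result["sites"], outdir / "sites.tsv", cfg)
        _write_table(result["xpclr"], outdir / "xpclr.tsv", cfg)
        _write_table(result["ihh12"], outdir / "ihh12.tsv", cfg)
        _write_table(result["hka"], outdir / "hka.tsv", cfg)
        _write_table(result["gene_stats"], outdir / "gene_stats.tsv", cfg, index=True)
        _write_table(result["calls"], outdir / "calls.tsv", cfg, index=True)
        if "ibs_dist" in result:
            dist, ids = result["ibs_dist"]
            ibstree.write_distance_tsv(dist, ids, outdir / "ibs_dist.tsv")
            (outdir / "tree.nwk").write_text(result["newick"] + "\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result["summary"], fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        log.exception("pipeline stage %r failed", stage)
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(stage + "\n")
        raise
    return result
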