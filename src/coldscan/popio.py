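"""Genotype I/O, site filtering, outgroup polarization and interval machinery.

Coordinate conventions used throughout the package:

* VCF ``POS`` is 1-based inclusive (the standard).
* Everything internal -- windows, gene intervals, sweep intervals -- is
  0-based half-open (BED convention).  A SNP at VCF position ``pos`` lives
  at internal coordinate ``pos - 1`` and overlaps ``[start, end)`` iff
  ``start <= pos - 1 < end``.

Haplotypes are stored as an int8 matrix of shape (2N, V) with allele codes
0 (REF), 1 (ALT) and -1 (missing).  Sample ``i`` of the ordered sample list
owns rows ``2i`` and ``2i + 1``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1
ROLES = ("focal", "reference", "outgroup")
EFFECT_CLASSES = ("regulatory", "missense", "synonymous", "other", "unknown")


# ---------------------------------------------------------------------------
# containers


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 haplotype alleles, two rows per diploid sample."""

    alleles: np.ndarray  # int8, shape (2N, V), -1 = missing
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"{self.alleles.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (expected 2 per sample)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def rows_for(self, samples: Iterable[str]) -> np.ndarray:
        """Haplotype row indices for the given samples, in their order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = []
        for s in samples:
            if s not in index:
                raise KeyError(f"sample {s!r} not in haplotype matrix")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return np.asarray(rows, dtype=np.intp)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, idx], list(self.sample_ids), self.phased)


@dataclass
class PopulationMap:
    """sample -> group and group -> role (focal / reference / outgroup)."""

    sample_group: dict[str, str]
    group_role: dict[str, str]

    def __post_init__(self) -> None:
        for g, r in self.group_role.items():
            if r not in ROLES:
                raise ValueError(f"group {g!r} has unknown role {r!r}")
        for s, g in self.sample_group.items():
            if g not in self.group_role:
                raise ValueError(f"sample {s!r} assigned to unmapped group {g!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "group", "role"], dtype=str)
        sg = dict(zip(df["sample"], df["group"]))
        gr = {}
        for g, r in zip(df["group"], df["role"]):
            if g in gr and gr[g] != r:
                raise ValueError(f"group {g!r} mapped to conflicting roles")
            gr[g] = r
        return cls(sg, gr)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, g in self.sample_group.items():
                fh.write(f"{s}\t{g}\t{self.group_role[g]}\n")

    def samples(self, role: str | None = None, group: str | None = None) -> list[str]:
        out = []
        for s, g in self.sample_group.items():
            if group is not None and g != group:
                continue
            if role is not None and self.group_role[g] != role:
                continue
            out.append(s)
        return out

    def groups(self, role: str | None = None) -> list[str]:
        return [g for g, r in self.group_role.items() if role is None or r == role]

    def require_scan_layout(self, need_outgroup: bool = False) -> None:
        """A two-population scan needs one focal and one reference group;
        polarization and HKA additionally need outgroup samples."""
        if len(self.groups("focal")) != 1 or len(self.groups("reference")) != 1:
            raise ValueError("scan requires exactly one focal and one reference group")
        if need_outgroup and not self.samples(role="outgroup"):
            raise ValueError("polarization/HKA require at least one outgroup sample")


@dataclass
class FilterReport:
    n_input: int
    n_fail_maf: int
    n_fail_missing: int
    n_kept: int


# ---------------------------------------------------------------------------
# VCF reading


def _new_variant_table(n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": pd.Series([""] * n, dtype=str),
        "pos": pd.Series(np.zeros(n, dtype=np.int64)),
        "id": pd.Series(["."] * n, dtype=str),
        "ref": pd.Series([""] * n, dtype=str),
        "alt": pd.Series([""] * n, dtype=str),
        "effect_class": pd.Series(["unknown"] * n, dtype=str),
        "ancestral_state": pd.Series(["unpolarized"] * n, dtype=str),
    })


def read_vcf(path: str | Path, popmap: PopulationMap | None = None,
             allow_unphased: bool = False) -> tuple[HaplotypeMatrix, pd.DataFrame, int]:
    """Read biallelic SNPs from a VCF into a haplotype matrix + variant table.

    Multi-allelic records and non-SNPs are skipped (the count is returned and
    logged).  If a popmap is supplied, columns are restricted to its samples;
    a popmap sample absent from the VCF is a hard error naming the sample.
    Returns ``(haplotypes, variants, n_skipped)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if popmap is not None:
        wanted = [s for s in popmap.sample_group]
        missing = [s for s in wanted if s not in vcf_samples]
        if missing:
            raise ValueError(f"popmap sample(s) absent from VCF: {', '.join(missing)}")
        keep = [s for s in vcf_samples if s in set(wanted)]
    else:
        keep = vcf_samples
    col = {s: i for i, s in enumerate(vcf_samples)}
    take = [col[s] for s in keep]

    rows: list[np.ndarray] = []
    recs: list[tuple] = []
    n_skipped = 0
    any_unphased = False
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        g = np.asarray(v.genotype.array(), dtype=np.int16)  # (n_samples, 3)
        g = g[take]
        if np.any((g[:, 2] == 0) & (g[:, 0] >= 0) & (g[:, 1] >= 0)):
            any_unphased = True
        hap = g[:, :2].reshape(-1).astype(np.int8)
        hap[hap < 0] = MISSING
        rows.append(hap)
        eff = v.INFO.get("EFFECT") or "unknown"
        recs.append((v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0], eff))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if any_unphased and not allow_unphased:
        raise ValueError("VCF contains unphased genotypes; pass allow_unphased=True "
                         "(haplotype-based statistics will refuse to run)")

    alleles = (np.stack(rows, axis=1) if rows
               else np.zeros((2 * len(keep), 0), dtype=np.int8))
    vt = _new_variant_table(len(recs))
    if recs:
        vt["chrom"] = [r[0] for r in recs]
        vt["pos"] = np.asarray([r[1] for r in recs], dtype=np.int64)
        vt["id"] = [r[2] for r in recs]
        vt["ref"] = [r[3] for r in recs]
        vt["alt"] = [r[4] for r in recs]
        vt["effect_class"] = [r[5] for r in recs]
    order = np.lexsort((vt["pos"].to_numpy(), vt["chrom"].to_numpy()))
    vt = vt.iloc[order].reset_index(drop=True)
    alleles = alleles[:, order]
    hm = HaplotypeMatrix(alleles, keep, phased=not any_unphased)
    return hm, vt, n_skipped


# ---------------------------------------------------------------------------
# filtering / polarization


def apply_filters(hm: HaplotypeMatrix, vt: pd.DataFrame,
                  popmap: PopulationMap | None = None,
                  maf: float = 0.05, max_missing: float = 0.2,
                  ) -> tuple[HaplotypeMatrix, pd.DataFrame, FilterReport]:
    """Retain sites with MAF >= ``maf`` and missing fraction <= ``max_missing``.

    Allele frequencies are computed over non-outgroup samples only, on called
    alleles (missing cells are excluded from the denominator).
    """
    if popmap is not None:
        ingroup = [s for s in hm.sample_ids
                   if popmap.group_role.get(popmap.sample_group.get(s, ""), "") != "outgroup"]
        rows = hm.rows_for(ingroup)
    else:
        rows = np.arange(hm.n_haplotypes)
    sub = hm.alleles[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    n_alt = (sub == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)
    maf_v = np.where(n_called > 0, np.minimum(p, 1.0 - p), 0.0)
    miss = 1.0 - n_called / len(rows)

    pass_maf = maf_v >= maf
    pass_miss = miss <= max_missing
    keep = pass_maf & pass_miss
    report = FilterReport(
        n_input=hm.n_sites,
        n_fail_maf=int((~pass_maf).sum()),
        n_fail_missing=int((~pass_miss).sum()),
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        log.warning("apply_filters: all %d sites removed", hm.n_sites)
    idx = np.flatnonzero(keep)
    return hm.take_sites(idx), vt.iloc[idx].reset_index(drop=True), report


def polarize(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
             min_outgroup: int = 2) -> pd.DataFrame:
    """Assign ancestral/derived states from the outgroup panel.

    A site is polarized iff at least ``min_outgroup`` outgroup samples are
    fully called and *every* called outgroup haplotype carries the same
    allele; that allele is ancestral, the other is derived.  Focal and
    reference genotypes are never inspected.
    """
    og = popmap.samples(role="outgroup")
    if not og:
        raise ValueError("polarize requires outgroup samples")
    rows = hm.rows_for(og)
    sub = hm.alleles[rows]  # (2K, V)
    called = sub != MISSING
    # sample fully called = both of its haplotype cells called
    pair_called = called[0::2] & called[1::2]
    n_samples_called = pair_called.sum(axis=0)
    n_ref = ((sub == 0) & called).sum(axis=0)
    n_alt = ((sub == 1) & called).sum(axis=0)
    unanimous_ref = (n_alt == 0) & (n_ref > 0)
    unanimous_alt = (n_ref == 0) & (n_alt > 0)
    ok = n_samples_called >= min_outgroup
    state = np.where(ok & unanimous_ref, "ref",
                     np.where(ok & unanimous_alt, "alt", "unpolarized"))
    out = vt.copy()
    out["ancestral_state"] = state
    return out


def derived_allele_code(vt: pd.DataFrame) -> np.ndarray:
    """Per-site derived allele code: 1 where ancestral is REF, 0 where ALT.

    Unpolarized sites default to the ALT allele (code 1); callers should mask
    them with ``polarized_mask`` where polarization matters.
    """
    anc = vt["ancestral_state"].to_numpy()
    return np.where(anc == "alt", 0, 1).astype(np.int8)


def polarized_mask(vt: pd.DataFrame) -> np.ndarray:
    return (vt["ancestral_state"].to_numpy() != "unpolarized")


# ---------------------------------------------------------------------------
# windows and gene intervals


def make_windows(contigs: Mapping[str, int], size: int = 50_000,
                 step: int = 25_000) -> pd.DataFrame:
    """Sliding windows tiling each contig (0-based half-open).

    Starts run 0, step, 2*step, ...; a final window anchored at
    ``length - size`` is appended when needed so every bp is covered.
    """
    if not (0 < step <= size):
        raise ValueError("require size >= step > 0")
    rows = []
    for chrom, length in contigs.items():
        if length <= 0:
            raise ValueError(f"contig {chrom!r} has non-positive length")
        if length <= size:
            starts = [0]
        else:
            starts = list(range(0, length - size + 1, step))
            if starts[-1] != length - size:
                starts.append(length - size)
        for s in starts:
            rows.append((chrom, s, min(s + size, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["id"] = [f"{c}:{s}-{e}" for c, s, e in zip(df.chrom, df.start, df.end)]
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     dtype={0: str, 1: np.int64, 2: np.int64, 3: str})
    if not df.sort_values(["chrom", "start"]).equals(df.reset_index(drop=True)):
        log.warning("read_bed: intervals not sorted; sorting internally")
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "name"]].to_csv(path, sep="\t", header=False, index=False)


def assign_to_genes(items: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Map intervals or SNPs onto gene intervals by half-open overlap.

    ``items`` needs columns ``chrom`` plus either ``start``/``end`` (half-open)
    or ``pos`` (1-based SNP position).  Returns a two-column frame
    ``(item, gene)`` of overlap pairs; items overlapping no gene are absent.
    ``item`` is the positional index into ``items``.
    """
    if {"start", "end"}.issubset(items.columns):
        s = items["start"].to_numpy(np.int64)
        e = items["end"].to_numpy(np.int64)
    elif "pos" in items.columns:
        # a SNP's position is compared directly against the half-open
        # interval: assigned iff start <= pos < end
        s = items["pos"].to_numpy(np.int64)
        e = s + 1
    else:
        raise ValueError("items need start/end or pos columns")
    chrom = items["chrom"].to_numpy(dtype=object)
    pairs_item: list[np.ndarray] = []
    pairs_gene: list[np.ndarray] = []
    for _, g in genes.iterrows():
        hit = (chrom == g["chrom"]) & (s < g["end"]) & (e > g["start"])
        idx = np.flatnonzero(hit)
        pairs_item.append(idx)
        pairs_gene.append(np.full(idx.size, g["name"], dtype=object))
    if pairs_item:
        return pd.DataFrame({
            "item": np.concatenate(pairs_item),
            "gene": np.concatenate(pairs_gene),
        })
    return pd.DataFrame({"item": [], "gene": []})
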