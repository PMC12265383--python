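"""Haplotype statistics: EHH decay around a core allele and the iHH12 scan.

EHH(x) is the probability that two random haplotypes carrying the core
allele are identical over the interval from the core out to offset x:
``sum_h C(n_h, 2) / C(n, 2)`` over the counts ``n_h`` of distinct extended
haplotypes, computed outward site by site in both directions.  EHH12 pools
the two most frequent extended-haplotype classes (computed over *all*
haplotypes at the core, allele-agnostic), which keeps power for soft sweeps;
iHH12 is its trapezoidal integral over physical distance (bp), summed over
both sides of the core.

Extension on each side truncates at the contig end, when the value drops
below ``cutoff`` (the sub-cutoff point is recorded and included in the
integral), when the gap to the next site exceeds ``max_gap``, or when fewer
than two haplotypes remain.  A haplotype with a missing call is dropped from
that side at the site where the missing call occurs, and the denominator is
recomputed over the survivors (conservative; keeps EHH well-defined).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import (MISSING, HaplotypeMatrix, PopulationMap,
                    derived_allele_code, polarized_mask)


@dataclass
class EhhCurve:
    core_pos: int
    allele: str
    offsets: np.ndarray      # signed bp offsets, ascending, includes 0
    ehh: np.ndarray          # values in [0, 1], 1.0 at offset 0
    trunc_left: str
    trunc_right: str

    def area(self) -> float:
        """Trapezoidal area under the curve over both sides, in bp."""
        i0 = int(np.searchsorted(self.offsets, 0))
        left = np.trapezoid(self.ehh[:i0 + 1], self.offsets[:i0 + 1])
        right = np.trapezoid(self.ehh[i0:], self.offsets[i0:])
        return float(left + right)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"core_pos": self.core_pos, "allele": self.allele,
                             "offset": self.offsets, "ehh": self.ehh})


def _pair_frac(counts: np.ndarray, pooled: bool) -> float:
    """Homozygosity from class counts; pools the top two classes for EHH12."""
    n = counts.sum()
    if n < 2:
        return 0.0
    if pooled and counts.size >= 2:
        top = np.sort(counts)[::-1]
        num = (top[0] + top[1]) * (top[0] + top[1] - 1) / 2.0
        num += float((top[2:] * (top[2:] - 1)).sum()) / 2.0
    else:
        num = float((counts * (counts - 1)).sum()) / 2.0
    return num / (n * (n - 1) / 2.0)


def _extend(alleles: np.ndarray, pos: np.ndarray, rows: np.ndarray,
            core: int, direction: int, cutoff: float, max_gap: int,
            pooled: bool, init_groups: np.ndarray
            ) -> tuple[list[float], list[float], str]:
    """Walk outward from the core, refining haplotype classes site by site."""
    offsets: list[float] = []
    values: list[float] = []
    cur = rows.copy()
    groups = init_groups.copy()
    j = core
    prev = pos[core]
    nsites = alleles.shape[1]
    while True:
        j += direction
        if j < 0 or j >= nsites:
            return offsets, values, "contig_end"
        if abs(pos[j] - prev) > max_gap:
            return offsets, values, "max_gap"
        a = alleles[cur, j]
        ok = a != MISSING
        if not ok.all():
            cur, groups, a = cur[ok], groups[ok], a[ok]
        if cur.size < 2:
            return offsets, values, "lost_haplotypes"
        _, groups = np.unique(groups * 2 + a, return_inverse=True)
        v = _pair_frac(np.bincount(groups), pooled)
        offsets.append(float(pos[j] - pos[core]))
        values.append(v)
        prev = pos[j]
        if v < cutoff:
            return offsets, values, "cutoff"


def _assemble(core_pos: int, allele: str, left: tuple, right: tuple) -> EhhCurve:
    lo, lv, lreason = left
    ro, rv, rreason = right
    offsets = np.array(lo[::-1] + [0.0] + ro)
    ehh = np.array(lv[::-1] + [1.0] + rv)
    return EhhCurve(core_pos, allele, offsets, ehh, lreason, rreason)


def ehh(hm: HaplotypeMatrix, vt: pd.DataFrame, core_index: int,
        allele: int | str, rows: np.ndarray | None = None,
        cutoff: float = 0.05, max_gap: int = 200_000) -> EhhCurve:
    """EHH curve around the core allele at site ``core_index``.

    ``allele`` is 0/1 or "derived"/"ancestral" (resolved through the variant
    table's ancestral state; the site must be polarized for the named forms).
    """
    if not hm.phased:
        raise ValueError("EHH requires phased haplotypes")
    label = str(allele)
    if allele in ("derived", "ancestral"):
        if not polarized_mask(vt)[core_index]:
            raise ValueError(f"site index {core_index} is unpolarized")
        der = int(derived_allele_code(vt)[core_index])
        allele = der if allele == "derived" else 1 - der
    allele = int(allele)
    if rows is None:
        rows = np.arange(hm.n_haplotypes)
    pos = vt["pos"].to_numpy().astype(np.int64)
    carriers = rows[hm.alleles[rows, core_index] == allele]
    if carriers.size < 2:
        raise ValueError(
            f"fewer than 2 carriers of allele {allele} at site "
            f"{vt['chrom'].iloc[core_index]}:{pos[core_index]}")
    init = np.zeros(carriers.size, dtype=np.int64)
    left = _extend(hm.alleles, pos, carriers, core_index, -1, cutoff, max_gap,
                   pooled=False, init_groups=init)
    right = _extend(hm.alleles, pos, carriers, core_index, +1, cutoff, max_gap,
                    pooled=False, init_groups=init)
    return _assemble(int(pos[core_index]), label, left, right)


def ehh12_curve(hm: HaplotypeMatrix, vt: pd.DataFrame, core_index: int,
                rows: np.ndarray | None = None, cutoff: float = 0.05,
                max_gap: int = 200_000) -> EhhCurve:
    """EHH12 curve (top-two haplotype classes pooled) over all haplotypes."""
    if not hm.phased:
        raise ValueError("EHH12 requires phased haplotypes")
    if rows is None:
        rows = np.arange(hm.n_haplotypes)
    pos = vt["pos"].to_numpy().astype(np.int64)
    a = hm.alleles[rows, core_index]
    keep = a != MISSING
    rows, a = rows[keep], a[keep]
    if np.unique(a).size != 2:
        raise ValueError(f"core site index {core_index} is not biallelic "
                         "among the selected haplotypes")
    init = a.astype(np.int64)
    left = _extend(hm.alleles, pos, rows, core_index, -1, cutoff, max_gap,
                   pooled=True, init_groups=init)
    right = _extend(hm.alleles, pos, rows, core_index, +1, cutoff, max_gap,
                    pooled=True, init_groups=init)
    return _assemble(int(pos[core_index]), "pooled-top2", left, right)


def ihh12_site(hm: HaplotypeMatrix, vt: pd.DataFrame, core_index: int,
               rows: np.ndarray | None = None, cutoff: float = 0.05,
               max_gap: int = 200_000) -> float:
    """Trapezoidal integral of EHH12 over bp, both sides of the core."""
    return ehh12_curve(hm, vt, core_index, rows, cutoff, max_gap).area()


def ihh12_scan(hm: HaplotypeMatrix, vt: pd.DataFrame,
               popmap: PopulationMap | None = None,
               rows: np.ndarray | None = None, cutoff: float = 0.05,
               max_gap: int = 200_000) -> pd.DataFrame:
    """iHH12 at every biallelic site; by default over focal haplotypes."""
    if rows is None:
        if popmap is None:
            rows = np.arange(hm.n_haplotypes)
        else:
            rows = hm.rows_for(popmap.samples(role="focal"))
    sub = hm.alleles[rows]
    called = sub != MISSING
    n1 = ((sub == 1) & called).sum(axis=0)
    n0 = ((sub == 0) & called).sum(axis=0)
    biallelic = (n0 > 0) & (n1 > 0)
    recs = []
    for j in np.flatnonzero(biallelic):
        recs.append((vt["chrom"].iloc[j], int(vt["pos"].iloc[j]),
                     ihh12_site(hm, vt, j, rows, cutoff, max_gap),
                     int(n0[j] + n1[j])))
    return pd.DataFrame(recs, columns=["chrom", "pos", "ihh12", "n_hap"])


def standardize_ihh12(table: pd.DataFrame, freq: np.ndarray | None = None,
                      n_bins: int = 10, min_sites: int = 50) -> pd.DataFrame:
    """Genome-wide z-scores; optional standardization within derived-frequency
    bins when ``freq`` is supplied."""
    out = table.copy()
    v = out["ihh12"].to_numpy(dtype=float)
    if v.size < min_sites:
        raise ValueError(f"standardize_ihh12 needs >= {min_sites} scored sites")
    z = np.zeros_like(v)
    if freq is None:
        sd = v.std()
        if sd == 0:
            import warnings
            warnings.warn("ihh12 values have zero variance; all z set to 0")
        else:
            z = (v - v.mean()) / sd
    else:
        freq = np.asarray(freq, dtype=float)
        edges = np.linspace(0, 1, n_bins + 1)
        which = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            m = which == b
            if m.sum() >= 2 and v[m].std() > 0:
                z[m] = (v[m] - v[m].mean()) / v[m].std()
    out["z"] = z
    return out
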