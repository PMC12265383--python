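"""Frequency-spectrum statistics: allele frequencies, ΔdAF, Hudson Fst and
nucleotide diversity π, per site and per window.

Estimator choices
-----------------
* Fst uses Hudson's two-population estimator with ratio-of-sums window
  aggregation, the standard for two-population sweep scans and robust in
  low-diversity windows.  Per site, with sample derived/alt frequencies
  ``p1, p2`` over ``n1, n2`` called alleles::

      N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      D = p1(1-p2) + p2(1-p1)

  and the windowed value is ``sum(N) / sum(D)`` over usable sites
  (n1, n2 >= 2 and D > 0).  Small negative values are expected under
  equality of frequencies (unbiasedness correction).
* π is the sample-size-corrected mean pairwise difference,
  ``sum_sites 2 p q n/(n-1)``, normalized by window length in bp.
* ``log2(pi_reference / pi_focal)`` maps a swept (zero-diversity) focal
  window to +inf, which deliberately ranks above all finite values.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .popio import (MISSING, HaplotypeMatrix, PopulationMap,
                    derived_allele_code, polarized_mask)


def _counts(alleles: np.ndarray, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt count, called count) per site over the given haplotype rows."""
    sub = alleles[rows]
    called = sub != MISSING
    return (sub == 1).sum(axis=0), called.sum(axis=0)


def allele_freq(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
                group: str) -> pd.DataFrame:
    """Derived-allele frequency per site within one group.

    Polarized sites report the derived allele; unpolarized sites report the
    ALT allele and are flagged ``polarized=False``.  Sites with no called
    alleles report NaN.
    """
    if group not in popmap.group_role:
        raise KeyError(f"group {group!r} not in population map")
    rows = hm.rows_for(popmap.samples(group=group))
    n_alt, n_called = _counts(hm.alleles, rows)
    der = derived_allele_code(vt)
    n_der = np.where(der == 1, n_alt, n_called - n_alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, n_der / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame({
        "chrom": vt["chrom"],
        "pos": vt["pos"],
        "id": vt["id"],
        "derived_count": n_der,
        "called": n_called,
        "freq": freq,
        "polarized": polarized_mask(vt),
    })


def delta_daf(freq_focal: np.ndarray | pd.Series,
              freq_reference: np.ndarray | pd.Series) -> np.ndarray:
    """ΔdAF = derived frequency (focal) - derived frequency (reference)."""
    return np.asarray(freq_focal, dtype=float) - np.asarray(freq_reference, dtype=float)


def hudson_site_components(hm: HaplotypeMatrix, popmap: PopulationMap
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator and usability mask."""
    popmap.require_scan_layout()
    r1 = hm.rows_for(popmap.samples(role="focal"))
    r2 = hm.rows_for(popmap.samples(role="reference"))
    a1, n1 = _counts(hm.alleles, r1)
    a2, n2 = _counts(hm.alleles, r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = a1 / np.maximum(n1, 1)
        p2 = a2 / np.maximum(n2, 1)
        N = ((p1 - p2) ** 2
             - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
             - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        D = p1 * (1 - p2) + p2 * (1 - p1)
    usable = (n1 >= 2) & (n2 >= 2) & (D > 0)
    return N, D, usable


def _window_slices(pos: np.ndarray, windows: pd.DataFrame) -> list[np.ndarray]:
    """Indices of sites falling in each half-open window (start <= pos < end,
    the same point-in-interval convention as gene assignment)."""
    out = []
    for start, end in zip(windows["start"].to_numpy(), windows["end"].to_numpy()):
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out.append(np.arange(lo, hi))
    return out


def hudson_fst_windowed(hm: HaplotypeMatrix, vt: pd.DataFrame,
                        popmap: PopulationMap, windows: pd.DataFrame
                        ) -> pd.DataFrame:
    """Ratio-of-sums Hudson Fst per window; windows with no usable site get NaN."""
    N, D, usable = hudson_site_components(hm, popmap)
    pos = vt["pos"].to_numpy()
    fst = np.full(len(windows), np.nan)
    n_sites = np.zeros(len(windows), dtype=int)
    for w, idx in enumerate(_window_slices(pos, windows)):
        idx = idx[usable[idx]]
        n_sites[w] = idx.size
        if idx.size:
            fst[w] = N[idx].sum() / D[idx].sum()
    out = windows.copy()
    out["fst"] = fst
    out["n_sites_fst"] = n_sites
    return out


def pi_sites(hm: HaplotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """Per-site 2pq * n/(n-1) over the given haplotype rows (0 where n < 2)."""
    n_alt, n = _counts(hm.alleles, rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = n_alt / np.maximum(n, 1)
        site_pi = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1)
    return np.where(n >= 2, site_pi, 0.0)


def pi_windowed(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
                group_or_role: str, windows: pd.DataFrame) -> np.ndarray:
    """Per-bp nucleotide diversity per window for a group or role."""
    if group_or_role in popmap.group_role:
        samples = popmap.samples(group=group_or_role)
    else:
        samples = popmap.samples(role=group_or_role)
        if not samples:
            raise KeyError(f"{group_or_role!r} is neither a group nor a role")
    site_pi = pi_sites(hm, hm.rows_for(samples))
    pos = vt["pos"].to_numpy()
    lengths = (windows["end"] - windows["start"]).to_numpy(float)
    return np.array([site_pi[idx].sum() for idx in _window_slices(pos, windows)]) / lengths


def log2_pi_ratio(pi_reference: np.ndarray | float,
                  pi_focal: np.ndarray | float) -> np.ndarray | float:
    """log2(pi_reference / pi_focal); +inf when focal diversity is exactly 0
    and reference is positive (the sweep limit); NaN for 0/0."""
    pr = np.asarray(pi_reference, dtype=float)
    pf = np.asarray(pi_focal, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(pr / pf)
    out = np.where((pf == 0) & (pr > 0), np.inf, out)
    out = np.where((pf == 0) & (pr == 0), np.nan, out)
    return out if out.ndim else float(out)


def window_stats(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
                 windows: pd.DataFrame) -> pd.DataFrame:
    """Windowed Fst, focal/reference π and log2 π-ratio in one table."""
    out = hudson_fst_windowed(hm, vt, popmap, windows)
    out["pi_focal"] = pi_windowed(hm, vt, popmap, "focal", windows)
    out["pi_reference"] = pi_windowed(hm, vt, popmap, "reference", windows)
    out["log2_pi_ratio"] = log2_pi_ratio(out["pi_reference"].to_numpy(),
                                         out["pi_focal"].to_numpy())
    pos = vt["pos"].to_numpy()
    out["n_sites"] = [idx.size for idx in _window_slices(pos, windows)]
    return out


def site_table(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap
               ) -> pd.DataFrame:
    """Per-site table with focal/reference derived frequencies and ΔdAF."""
    popmap.require_scan_layout()
    focal = popmap.groups("focal")[0]
    ref = popmap.groups("reference")[0]
    ff = allele_freq(hm, vt, popmap, focal)
    fr = allele_freq(hm, vt, popmap, ref)
    return pd.DataFrame({
        "chrom": vt["chrom"],
        "pos": vt["pos"],
        "id": vt["id"],
        "effect_class": vt["effect_class"],
        "polarized": ff["polarized"],
        "daf_focal": ff["freq"],
        "daf_reference": fr["freq"],
        "delta_daf": delta_daf(ff["freq"], fr["freq"]),
    })
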