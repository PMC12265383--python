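"""HKA-like polymorphism-versus-divergence test.

Under neutrality, within-population polymorphism and between-species fixed
divergence accumulate in proportion; a selective sweep removes polymorphism
much faster than divergence.  Per unit (gene or window) we count

* ``P``: sites polymorphic among focal-population haplotypes, and
* ``D``: sites where the focal population is fixed for one allele while all
  called outgroup haplotypes are fixed for the other,

then test each unit's (P, D) against the genome-wide totals with a 2x2
chi-square (no continuity correction).  The signed score is ``+sqrt(chi2)``
when polymorphism is deficient (the sweep direction) and ``-sqrt(chi2)``
when it is in excess.  Units whose divergence count does not exceed
``divergence_min`` are marked unusable and excluded from ranking.

``polarized_site_scan`` is the site-level variant used around a focal SNP:
over sliding sub-windows it contrasts derived polymorphic sites against
polarized divergent sites (focal fixed derived), scoring each sub-window
against the totals of the scanned region.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .popio import (MISSING, HaplotypeMatrix, PopulationMap, assign_to_genes,
                    derived_allele_code, polarized_mask)


def site_classes(hm: HaplotypeMatrix, popmap: PopulationMap,
                 min_outgroup: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site flags (is_polymorphic_in_focal, is_fixed_difference).

    Fixing claims require >= 2 called focal alleles; a site with missing
    outgroup calls still counts toward D if at least ``min_outgroup``
    outgroup samples are called and unanimous.
    """
    rf = hm.rows_for(popmap.samples(role="focal"))
    ro = hm.rows_for(popmap.samples(role="outgroup"))
    f = hm.alleles[rf]
    f_called = f != MISSING
    f0 = ((f == 0) & f_called).sum(axis=0)
    f1 = ((f == 1) & f_called).sum(axis=0)
    is_p = (f0 > 0) & (f1 > 0)
    fixed0 = (f0 >= 2) & (f1 == 0)
    fixed1 = (f1 >= 2) & (f0 == 0)

    o = hm.alleles[ro]
    o_called = o != MISSING
    pair_called = o_called[0::2] & o_called[1::2]
    og_ok = pair_called.sum(axis=0) >= min_outgroup
    o0 = ((o == 0) & o_called).sum(axis=0)
    o1 = ((o == 1) & o_called).sum(axis=0)
    og_fixed0 = og_ok & (o1 == 0) & (o0 > 0)
    og_fixed1 = og_ok & (o0 == 0) & (o1 > 0)
    is_d = (fixed0 & og_fixed1) | (fixed1 & og_fixed0)
    return is_p, is_d


def count_pd(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
             units: pd.DataFrame, min_outgroup: int = 2) -> pd.DataFrame:
    """P and D counts per unit interval (columns chrom/start/end/name)."""
    is_p, is_d = site_classes(hm, popmap, min_outgroup)
    pairs = assign_to_genes(vt, units)
    out = units[["name"]].copy().rename(columns={"name": "unit"})
    P = np.zeros(len(units), dtype=int)
    D = np.zeros(len(units), dtype=int)
    unit_index = {n: i for i, n in enumerate(units["name"])}
    if len(pairs):
        items = pairs["item"].to_numpy(dtype=int)
        us = pairs["gene"].map(unit_index).to_numpy(dtype=int)
        np.add.at(P, us, is_p[items])
        np.add.at(D, us, is_d[items])
    out["P"] = P
    out["D"] = D
    return out


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square of [[a, b], [c, d]] without continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    if total == 0:
        return 0.0
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if np.any(exp == 0):
        return 0.0
    return float(((table - exp) ** 2 / exp).sum())


def hka_test(records: pd.DataFrame, divergence_min: int = 60) -> pd.DataFrame:
    """Per-unit 2x2 chi-square against genome totals over usable units.

    ``records`` has columns unit/P/D; a unit is usable iff
    ``D > divergence_min`` (strict).
    """
    out = records.copy()
    out["usable"] = out["D"] > divergence_min
    use = out["usable"].to_numpy()
    P_tot = int(out.loc[use, "P"].sum())
    D_tot = int(out.loc[use, "D"].sum())
    if P_tot == 0 or D_tot == 0:
        raise ValueError(f"degenerate genome totals (P_tot={P_tot}, D_tot={D_tot})")
    expected = np.full(len(out), np.nan)
    chi2 = np.full(len(out), np.nan)
    signed = np.full(len(out), np.nan)
    ratio_tot = P_tot / (P_tot + D_tot)
    for i, rec in out.iterrows():
        if not rec["usable"]:
            continue
        P, D = int(rec["P"]), int(rec["D"])
        expected[i] = (P + D) * ratio_tot
        c2 = _chi2_2x2(P, D, P_tot - P, D_tot - D)
        chi2[i] = c2
        unit_ratio = P / (P + D) if P + D else ratio_tot
        signed[i] = np.sqrt(c2) if unit_ratio < ratio_tot else -np.sqrt(c2)
    out["expected_P"] = expected
    out["chi2"] = chi2
    out["signed_score"] = signed
    return out


def polarized_site_scan(hm: HaplotypeMatrix, vt: pd.DataFrame,
                        popmap: PopulationMap, center: int, radius: int,
                        window_size: int = 50_000, step: int = 10_000
                        ) -> pd.DataFrame:
    """Signed polymorphism-deficiency curve in sub-windows around ``center``.

    Uses polarized sites only: derived polymorphic sites in the focal
    population versus sites where the focal population is fixed for the
    derived allele.  Each sub-window is scored against the totals of the
    scanned region; positive = polymorphism deficit (sweep direction).
    ``center`` is a 1-based variant position.
    """
    pol = polarized_mask(vt)
    der = derived_allele_code(vt)
    rf = hm.rows_for(popmap.samples(role="focal"))
    f = hm.alleles[rf]
    f_called = f != MISSING
    f0 = ((f == 0) & f_called).sum(axis=0)
    f1 = ((f == 1) & f_called).sum(axis=0)
    n_der = np.where(der == 1, f1, f0)
    n_anc = np.where(der == 1, f0, f1)
    is_poly = pol & (n_der > 0) & (n_anc > 0)
    is_div = pol & (n_der >= 2) & (n_anc == 0)

    pos0 = vt["pos"].to_numpy()
    lo = max(0, center - radius)
    hi = center + radius
    in_range = (pos0 >= lo) & (pos0 < hi)
    if not (pol & in_range).any():
        return pd.DataFrame(columns=["start", "end", "P", "D", "signed_score"])
    P_tot = int(is_poly[in_range].sum())
    D_tot = int(is_div[in_range].sum())
    rows = []
    ratio_tot = P_tot / (P_tot + D_tot) if P_tot + D_tot else np.nan
    for start in range(lo, hi - window_size + 1, step):
        end = start + window_size
        m = (pos0 >= start) & (pos0 < end)
        P = int(is_poly[m].sum())
        D = int(is_div[m].sum())
        if P + D == 0 or P_tot + D_tot == 0:
            score = np.nan
        else:
            c2 = _chi2_2x2(P, D, P_tot - P, D_tot - D)
            score = np.sqrt(c2) if P / (P + D) < ratio_tot else -np.sqrt(c2)
        rows.append((start, end, P, D, score))
    return pd.DataFrame(rows, columns=["start", "end", "P", "D", "signed_score"])
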