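"""Shared builders and independent brute-force oracles for the test suite.

Oracles here deliberately re-derive each statistic from its definition
(explicit loops, pair enumeration, partition refinement on strings) and are
kept independent of the library's vectorized implementations.
"""
from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from coldscan.popio import MISSING, HaplotypeMatrix, PopulationMap


def hm_from_rows(rows, prefix: str = "s") -> HaplotypeMatrix:
    a = np.asarray(rows, dtype=np.int8)
    assert a.shape[0] % 2 == 0, "need an even number of haplotype rows"
    ids = [f"{prefix}{i + 1:02d}" for i in range(a.shape[0] // 2)]
    return HaplotypeMatrix(a, ids)


def vt_for(positions, chrom: str = "1", ancestral=None, effect=None) -> pd.DataFrame:
    positions = list(positions)
    n = len(positions)
    vt = pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": np.asarray(positions, dtype=np.int64),
        "id": ["."] * n,
        "ref": ["A"] * n,
        "alt": ["T"] * n,
        "effect_class": (["unknown"] * n if effect is None else list(effect)),
        "ancestral_state": (["ref"] * n if ancestral is None else list(ancestral)),
    })
    return vt


def popmap_for(n_focal: int, n_reference: int, n_outgroup: int,
               prefix: str = "s") -> PopulationMap:
    """Roles assigned over consecutive sample ids s01, s02, ..."""
    sg = {}
    i = 0
    for _ in range(n_focal):
        i += 1
        sg[f"{prefix}{i:02d}"] = "cold"
    for _ in range(n_reference):
        i += 1
        sg[f"{prefix}{i:02d}"] = "warm"
    for _ in range(n_outgroup):
        i += 1
        sg[f"{prefix}{i:02d}"] = "outgroup"
    return PopulationMap(sg, {"cold": "focal", "warm": "reference",
                              "outgroup": "outgroup"})


# ---------------------------------------------------------------------------
# brute-force oracles


def hudson_fst_oracle(focal_rows, ref_rows) -> float:
    """Literal site-by-site Hudson formula, ratio of sums, plain loops."""
    num = den = 0.0
    V = len(focal_rows[0])
    for j in range(V):
        a1 = [r[j] for r in focal_rows if r[j] != MISSING]
        a2 = [r[j] for r in ref_rows if r[j] != MISSING]
        n1, n2 = len(a1), len(a2)
        if n1 < 2 or n2 < 2:
            continue
        p1, p2 = sum(a1) / n1, sum(a2) / n2
        D = p1 * (1 - p2) + p2 * (1 - p1)
        if D <= 0:
            continue
        N = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
        num += N
        den += D
    return num / den


def pi_oracle(rows, length: float) -> float:
    """Mean pairwise per-bp difference over all haplotype pairs (no missing)."""
    rows = [list(r) for r in rows]
    pairs = list(combinations(range(len(rows)), 2))
    total = 0.0
    for i, j in pairs:
        total += sum(1 for a, b in zip(rows[i], rows[j]) if a != b)
    return total / len(pairs) / length


def _homozygosity(classes: list, pooled: bool) -> float:
    counts = sorted((classes.count(c) for c in set(classes)), reverse=True)
    n = sum(counts)
    if n < 2:
        return 0.0
    if pooled and len(counts) >= 2:
        num = comb(counts[0] + counts[1], 2) + sum(comb(c, 2) for c in counts[2:])
    else:
        num = sum(comb(c, 2) for c in counts)
    return num / comb(n, 2)


def ehh_curve_oracle(alleles, positions, core: int, carriers,
                     cutoff: float, max_gap: int, pooled: bool,
                     init_core: bool | None = None):
    """String-based partition-refinement EHH/EHH12, both sides.

    Returns (offsets, values) sorted ascending, including (0, 1.0).  Mirrors
    the package's truncation and missing-data dropping rules but shares no
    code with it.
    """
    alleles = np.asarray(alleles)
    if init_core is None:
        init_core = pooled
    out = [(0.0, 1.0)]
    for direction in (-1, +1):
        if init_core:
            survivors = {h: str(alleles[h, core]) for h in carriers}
        else:
            survivors = {h: "" for h in carriers}
        j, prev = core, positions[core]
        while True:
            j += direction
            if j < 0 or j >= alleles.shape[1]:
                break
            if abs(positions[j] - prev) > max_gap:
                break
            survivors = {h: s + str(alleles[h, j]) for h, s in survivors.items()
                         if alleles[h, j] != MISSING}
            if len(survivors) < 2:
                break
            v = _homozygosity(list(survivors.values()), pooled)
            out.append((float(positions[j] - positions[core]), v))
            prev = positions[j]
            if v < cutoff:
                break
    out.sort()
    return np.array([o for o, _ in out]), np.array([v for _, v in out])


def ihh12_oracle(alleles, positions, core: int, rows,
                 cutoff: float, max_gap: int) -> float:
    """Trapezoidal integral of the oracle EHH12 curve, both sides."""
    offs, vals = ehh_curve_oracle(alleles, positions, core, rows,
                                  cutoff, max_gap, pooled=True)
    i0 = int(np.searchsorted(offs, 0))
    total = 0.0
    for a, b in zip(range(i0, len(offs) - 1), range(i0 + 1, len(offs))):
        total += (vals[a] + vals[b]) / 2 * (offs[b] - offs[a])
    for a, b in zip(range(i0, 0, -1), range(i0 - 1, -1, -1)):
        total += (vals[a] + vals[b]) / 2 * (offs[a] - offs[b])
    return total
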