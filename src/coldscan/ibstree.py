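"""Identity-by-state distances and neighbor-joining tree for population
structure sanity checks.

The distance is the PLINK ``1-ibs`` convention on diploid allele dosages:
``d(i, j) = mean_sites |dosage_i - dosage_j| / 2`` over pairwise-complete
sites, so identical genotypes are at distance 0 and opposite homozygotes at
1.  The tree is canonical Saitou-Nei neighbor joining; negative branch
lengths are clamped to 0 with the excess moved to the sister branch.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .popio import MISSING, HaplotypeMatrix


def thin_variants(vt: pd.DataFrame, count: int, seed: int) -> np.ndarray:
    """Order-preserving uniform random subset of site indices."""
    V = len(vt)
    if count >= V:
        if count > V:
            import warnings
            warnings.warn(f"thin count {count} exceeds {V} sites; keeping all")
        return np.arange(V)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(V, size=count, replace=False))


def genotype_dosage(hm: HaplotypeMatrix) -> np.ndarray:
    """ALT-allele dosage matrix (N, V): 0/1/2, or -1 when either cell missing."""
    a = hm.alleles
    h1, h2 = a[0::2], a[1::2]
    dos = (h1 + h2).astype(np.int8)
    dos[(h1 == MISSING) | (h2 == MISSING)] = MISSING
    return dos


def ibs_distance(dosage: np.ndarray) -> np.ndarray:
    """Symmetric 1-IBS distance matrix over pairwise-complete sites."""
    dos = np.asarray(dosage)
    n = dos.shape[0]
    called = dos != MISSING
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = called[i] & called[j]
            if not m.any():
                raise ValueError(f"samples {i} and {j} share no called sites")
            d[i, j] = d[j, i] = np.abs(dos[i, m] - dos[j, m]).mean() / 2.0
    return d


def _fmt(x: float) -> str:
    return f"{max(x, 0.0):.6g}"


def nj_tree(dist: np.ndarray, ids: list[str]) -> str:
    """Newick string from a complete distance matrix (Saitou-Nei NJ)."""
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes = list(ids)
    while len(nodes) > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        # clamp negatives, moving the excess to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dk[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    return (f"({nodes[0]}:{_fmt(la)},{nodes[1]}:{_fmt(lb)},"
            f"{nodes[2]}:{_fmt(lc)});")


def write_distance_tsv(dist: np.ndarray, ids: list[str], path) -> None:
    pd.DataFrame(dist, index=ids, columns=ids).to_csv(path, sep="\t")
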