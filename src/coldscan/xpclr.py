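"""Cross-population composite likelihood ratio (XP-CLR) scan.

Model
-----
The focal population's derived-allele frequency at each SNP is modelled as a
Brownian-drift perturbation of the reference frequency ``p1``:

* Neutral: ``p2 ~ Normal(p1, omega * p1 * (1 - p1))`` truncated to ``[0, 1]``
  with the escaped tail mass placed as point masses at 0 and 1; the observed
  derived count is ``x ~ Binomial(k, p2)``.  The marginal ``P(x | p1)`` is
  evaluated by Gauss-Legendre quadrature (64 points over ``p1 +/- 8 sd``,
  clipped to [0, 1]) plus the boundary terms.
* Selection at position ``tau`` with strength ``s``: a SNP at distance ``d``
  escapes the sweep with probability ``c = 1 - exp(-rho * d / s)``; with
  probability ``1 - c`` it is dragged to fixation of whichever allele rode
  the sweep (derived with probability ``p1``, ancestral otherwise), i.e. the
  drift density mass moves to ``p2 = 1`` with weight ``p1`` and to
  ``p2 = 0`` with weight ``1 - p1``.  The selection marginal is the mixture
  ``c * neutral + (1 - c) * (p1 * 1{x=k} + (1-p1) * 1{x=0})``.

``CLR(tau) = 2 * max_s sum_j w_j (log sel_j - log neut_j)`` floored at 0 (the
neutral point is always included in the maximization), with LD down-weighting
``w_j = 1 / #{SNPs in the window with r^2 > 0.95 to j}``.

The drift variance ``omega`` is a genome-wide method-of-moments estimate:
``Var(p_focal - p_reference) = omega * mean[pbar (1 - pbar)]`` with
``pbar`` the reference frequency.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, ndtr

from .popio import (MISSING, HaplotypeMatrix, PopulationMap,
                    derived_allele_code, polarized_mask)

OMEGA_MIN, OMEGA_MAX = 1e-6, 1.0
_TINY = 1e-300


def default_s_grid(n: int = 20) -> np.ndarray:
    """Logarithmic selection-coefficient grid over [1e-5, 0.5]."""
    return np.logspace(np.log10(1e-5), np.log10(0.5), n)


def estimate_omega(freqs_focal: np.ndarray, freqs_reference: np.ndarray) -> float:
    """Method-of-moments drift variance from genome-wide frequency pairs."""
    p1 = np.asarray(freqs_focal, dtype=float)
    p2 = np.asarray(freqs_reference, dtype=float)
    ok = np.isfinite(p1) & np.isfinite(p2) & (p2 > 0) & (p2 < 1)
    if ok.sum() < 10:
        raise ValueError(f"estimate_omega needs >= 10 usable sites, got {ok.sum()}")
    num = float(np.var(p1[ok] - p2[ok]))
    den = float(np.mean(p2[ok] * (1 - p2[ok])))
    return float(np.clip(num / den, OMEGA_MIN, OMEGA_MAX))


@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def drift_nodes(p1: np.ndarray, omega: float, n_points: int = 64
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature nodes/weights (density included) plus boundary masses.

    Returns ``(t, wt, m0, m1)`` with shapes ``(S, n)`` for the nodes/weights
    and ``(S,)`` for the point masses at 0 and 1.  The integration range is
    ``p1 +/- 8 sd`` clipped to [0, 1] so narrow densities are resolved.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    sd = np.sqrt(omega * p1 * (1 - p1))
    sd = np.maximum(sd, 1e-12)
    lo = np.clip(p1 - 8 * sd, 0.0, 1.0)
    hi = np.clip(p1 + 8 * sd, 0.0, 1.0)
    x, w = _leggauss(n_points)
    half = (hi - lo)[:, None] / 2.0
    t = lo[:, None] + (x[None, :] + 1.0) * half
    dens = np.exp(-0.5 * ((t - p1[:, None]) / sd[:, None]) ** 2) / (
        sd[:, None] * np.sqrt(2 * np.pi))
    wt = w[None, :] * half * dens
    m0 = ndtr((0.0 - p1) / sd)
    m1 = 1.0 - ndtr((1.0 - p1) / sd)
    return t, wt, m0, m1


def drift_total_mass(p1: float | np.ndarray, omega: float,
                     n_points: int = 64) -> np.ndarray:
    """Total probability mass of the truncated drift density (should be 1)."""
    t, wt, m0, m1 = drift_nodes(p1, omega, n_points)
    return wt.sum(axis=1) + m0 + m1


def neutral_marginal(x: np.ndarray, k: np.ndarray, p1: np.ndarray,
                     omega: float, n_points: int = 64) -> np.ndarray:
    """P(x | p1) under neutral drift, vectorized over sites."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    t, wt, m0, m1 = drift_nodes(p1, omega, n_points)
    t = np.clip(t, 1e-12, 1 - 1e-12)
    logpmf = (gammaln(k + 1)[:, None] - gammaln(x + 1)[:, None]
              - gammaln(k - x + 1)[:, None]
              + x[:, None] * np.log(t) + (k - x)[:, None] * np.log1p(-t))
    A = (wt * np.exp(logpmf)).sum(axis=1)
    A = A + m0 * (x == 0) + m1 * (x == k)
    return A


def ld_weights(haps: np.ndarray, r2_threshold: float = 0.95) -> np.ndarray:
    """w_j = 1 / (number of SNPs in the set with r^2 > threshold to j).

    ``haps`` is a (H, m) 0/1 matrix (missing -1 mean-imputed).  The count
    includes SNP j itself, so weights are in (0, 1].
    """
    h = haps.astype(float)
    h[haps == MISSING] = np.nan
    colmean = np.nanmean(h, axis=0)
    inds = np.where(np.isnan(h))
    h[inds] = np.take(colmean, inds[1])
    h = h - h.mean(axis=0)
    denom = np.sqrt((h ** 2).sum(axis=0))
    denom[denom == 0] = 1.0
    h = h / denom
    r2 = (h.T @ h) ** 2
    counts = (r2 > r2_threshold).sum(axis=1)
    return 1.0 / np.maximum(counts, 1)


def xpclr_scan(hm: HaplotypeMatrix, vt: pd.DataFrame, popmap: PopulationMap,
               omega: float | None = None,
               rho: float = 1e-8,
               grid_spacing: int = 10_000,
               window_radius: int = 250_000,
               max_snps: int = 200,
               s_grid: np.ndarray | None = None,
               n_points: int = 64,
               contig_length: int | None = None) -> pd.DataFrame:
    """CLR over a grid of putative selected positions on one contig.

    Only polarized sites enter the model (it is defined on derived
    frequencies).  Grid points with no SNP in the window get NaN.
    """
    popmap.require_scan_layout()
    if s_grid is None:
        s_grid = default_s_grid()
    pol = polarized_mask(vt)
    der = derived_allele_code(vt)

    rf = hm.rows_for(popmap.samples(role="focal"))
    rr = hm.rows_for(popmap.samples(role="reference"))
    sub_f, sub_r = hm.alleles[rf], hm.alleles[rr]
    called_f = sub_f != MISSING
    called_r = sub_r != MISSING
    k = called_f.sum(axis=0).astype(float)
    x_alt = ((sub_f == 1) & called_f).sum(axis=0).astype(float)
    x = np.where(der == 1, x_alt, k - x_alt)
    kr = called_r.sum(axis=0).astype(float)
    xr_alt = ((sub_r == 1) & called_r).sum(axis=0).astype(float)
    xr = np.where(der == 1, xr_alt, kr - xr_alt)

    use = pol & (k >= 2) & (kr >= 2)
    idx = np.flatnonzero(use)
    idx = idx[np.argsort(vt["pos"].to_numpy()[idx], kind="stable")]
    pos = vt["pos"].to_numpy()[idx].astype(float) - 1.0
    x, k = x[idx], k[idx]
    p1 = xr[idx] / kr[idx]
    eps = 1.0 / (kr[idx] + 1.0)
    p1 = np.clip(p1, eps, 1 - eps)

    if omega is None:
        omega = estimate_omega(x / k, p1)

    A = neutral_marginal(x, k, p1, omega, n_points)
    A = np.maximum(A, _TINY)
    logA = np.log(A)
    B = p1 * (x == k) + (1 - p1) * (x == 0)

    pooled = hm.alleles[np.concatenate([rf, rr])]
    chrom = vt["chrom"].iloc[0] if len(vt) else "NA"
    if contig_length is None:
        contig_length = int(vt["pos"].max()) if len(vt) else 0
    grid = np.arange(grid_spacing // 2, contig_length, grid_spacing, dtype=float)

    clr = np.full(grid.size, np.nan)
    s_hat = np.full(grid.size, np.nan)
    n_snps = np.zeros(grid.size, dtype=int)
    for gi, tau in enumerate(grid):
        lo = np.searchsorted(pos, tau - window_radius, side="left")
        hi = np.searchsorted(pos, tau + window_radius, side="right")
        sel = np.arange(lo, hi)
        if sel.size == 0:
            continue
        d = np.abs(pos[sel] - tau)
        if sel.size > max_snps:
            keep = np.argpartition(d, max_snps)[:max_snps]
            sel = sel[keep]
            d = d[keep]
        w = ld_weights(pooled[:, idx[sel]])
        c = 1.0 - np.exp(-rho * d[None, :] / s_grid[:, None])   # (n_s, m)
        mix = c * A[sel][None, :] + (1.0 - c) * B[sel][None, :]
        ll = np.log(np.maximum(mix, _TINY)) - logA[sel][None, :]
        scores = (w[None, :] * ll).sum(axis=1)
        best = int(np.argmax(scores))
        clr[gi] = 2.0 * max(scores[best], 0.0)
        s_hat[gi] = s_grid[best] if scores[best] > 0 else np.nan
        n_snps[gi] = sel.size
    return pd.DataFrame({"chrom": chrom, "grid_pos": grid.astype(int),
                         "clr": clr, "s_hat": s_hat, "n_snps": n_snps})
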