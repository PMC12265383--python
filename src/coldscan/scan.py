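"""Combine the four methods: gene-level aggregation, empirical-percentile
outlier calls, >= 3-of-4 intersection and per-class top-ΔdAF variants.

Methods and their gene-level raw values:

* ``fst_pi``   -- max windowed Hudson Fst AND max log2 π-ratio over windows
  overlapping the gene (a paired method: the outlier call requires *both*
  components in their top ``q_pair``).
* ``xpclr_pi`` -- max CLR over grid points inside the gene, paired with the
  same π-ratio component.
* ``ihh12``    -- max standardized iHH12 z over sites in the gene.
* ``hka``      -- the gene unit's signed polymorphism-deficiency score
  (missing when the unit's divergence count is below the usability cut).

Percentiles are empirical with average ranks for ties, computed over genes
with non-missing values; a gene is an outlier when its percentile strictly
exceeds ``1 - q``.  Aggregation over windows uses max, not mean: sweep
signals are local and a mean dilutes sub-gene peaks.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .popio import assign_to_genes

METHODS = ("fst_pi", "xpclr_pi", "ihh12", "hka")


def _gene_max(values: np.ndarray, items: pd.DataFrame, genes: pd.DataFrame
              ) -> pd.Series:
    """Max of per-item values over the items overlapping each gene."""
    pairs = assign_to_genes(items, genes)
    out = pd.Series(np.nan, index=genes["name"], dtype=float)
    if len(pairs):
        v = pd.Series(values[pairs["item"].to_numpy(dtype=int)])
        grp = v.groupby(pairs["gene"].to_numpy()).max()
        out.loc[grp.index] = grp.to_numpy()
    return out


def aggregate_to_genes(genes: pd.DataFrame,
                       window_stats: pd.DataFrame,
                       xpclr_grid: pd.DataFrame,
                       ihh12_table: pd.DataFrame,
                       hka_records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene raw statistics for the four methods (NaN = no data)."""
    out = pd.DataFrame(index=pd.Index(genes["name"], name="gene"))
    out["fst"] = _gene_max(window_stats["fst"].to_numpy(float), window_stats, genes)
    out["pi_ratio"] = _gene_max(window_stats["log2_pi_ratio"].to_numpy(float),
                                window_stats, genes)
    gx = xpclr_grid.rename(columns={"grid_pos": "pos"})
    out["clr"] = _gene_max(gx["clr"].to_numpy(float), gx, genes)
    out["ihh12_z"] = _gene_max(ihh12_table["z"].to_numpy(float), ihh12_table, genes)
    hka = hka_records.set_index("unit")
    score = hka["signed_score"].where(hka["usable"])
    out["hka"] = score.reindex(out.index).to_numpy()
    return out


def percentile_ranks(values: np.ndarray | pd.Series) -> np.ndarray:
    """Empirical percentile in (0, 1] with average ranks for ties; NaN-aware."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)  # +/-inf participate in ranking
    if ok.sum():
        out[ok] = rankdata(v[ok], method="average") / ok.sum()
    return out


def call_outliers(gene_stats: pd.DataFrame, q_pair: float = 0.05,
                  q_site: float = 0.01, pair_mode: str = "joint") -> pd.DataFrame:
    """Outlier flags per method from empirical percentiles.

    ``pair_mode="joint"`` (default) requires both component statistics of a
    paired method in their top ``q_pair``; ``"ranksum"`` flags the top
    ``q_pair`` by summed component ranks instead.
    """
    if pair_mode not in ("joint", "ranksum"):
        raise ValueError("pair_mode must be 'joint' or 'ranksum'")
    out = gene_stats.copy()
    for col in ("fst", "pi_ratio", "clr", "ihh12_z", "hka"):
        out[f"pct_{col}"] = percentile_ranks(gene_stats[col])
    if pair_mode == "joint":
        out["fst_pi"] = ((out["pct_fst"] > 1 - q_pair)
                         & (out["pct_pi_ratio"] > 1 - q_pair))
        out["xpclr_pi"] = ((out["pct_clr"] > 1 - q_pair)
                           & (out["pct_pi_ratio"] > 1 - q_pair))
    else:
        for method, col in (("fst_pi", "pct_fst"), ("xpclr_pi", "pct_clr")):
            combined = out[col] + out["pct_pi_ratio"]
            pct = percentile_ranks(combined)
            out[method] = pct > 1 - q_pair
    out["ihh12"] = out["pct_ihh12_z"] > 1 - q_site
    out["hka"] = out["pct_hka"] > 1 - q_site
    for m in METHODS:
        out[m] = out[m].fillna(False).astype(bool)
    return out


def intersect_methods(flags: pd.DataFrame) -> pd.DataFrame:
    """Candidate calls: support count, >=3-method candidate and 4-method
    strict flags."""
    out = pd.DataFrame(index=flags.index)
    for m in METHODS:
        out[m] = flags[m].astype(bool)
    out["n_support"] = out[list(METHODS)].sum(axis=1)
    out["candidate"] = out["n_support"] >= 3
    out["strict"] = out["n_support"] == 4
    return out


_CLASS_ALIASES = {
    "regulatory": ("regulatory",),
    "exonic": ("missense",),       # protein-altering exonic sites
    "missense": ("missense",),
}


def top_variants(site_table: pd.DataFrame, genes: pd.DataFrame,
                 calls: pd.DataFrame, min_support: int = 4,
                 classes: tuple[str, ...] = ("regulatory", "exonic")
                 ) -> dict[str, dict | None]:
    """Per-effect-class ΔdAF leaders among supported candidate genes.

    Only polarized sites inside genes whose support count reaches
    ``min_support`` are ranked.  Ties on ΔdAF are all reported; the leader
    is the smallest genomic coordinate.
    """
    wanted = set(calls.index[calls["n_support"] >= min_support])
    pairs = assign_to_genes(site_table, genes)
    in_gene = pairs[pairs["gene"].isin(wanted)]
    sites = site_table.iloc[np.unique(in_gene["item"].to_numpy(dtype=int))] \
        if len(in_gene) else site_table.iloc[[]]
    sites = sites[sites["polarized"].astype(bool)]
    leaders: dict[str, dict | None] = {}
    for cls in classes:
        members = _CLASS_ALIASES.get(cls, (cls,))
        sub = sites[sites["effect_class"].isin(members)]
        sub = sub[np.isfinite(sub["delta_daf"].astype(float))]
        if not len(sub):
            leaders[cls] = None
            continue
        best = sub["delta_daf"].max()
        ties = sub[sub["delta_daf"] == best].sort_values("pos")
        lead = ties.iloc[0]
        leaders[cls] = {
            "pos": int(lead["pos"]),
            "id": str(lead["id"]),
            "delta_daf": float(best),
            "ties": [int(p) for p in ties["pos"]],
        }
    return leaders
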