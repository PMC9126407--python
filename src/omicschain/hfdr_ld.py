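"""Hierarchical FDR across cis regions and LD-based priority pruning.

Implements the two-level selective-inference scheme used for QTL
discovery across many gene regions: within each region the variant
p-values are Benjamini–Hochberg adjusted and the minimum adjusted value
(the Simes p-value) summarizes the region; BH across the m region-level
Simes p-values at level α₁ selects k regions; within selected regions
variants are declared significant when their within-region BH-adjusted
p-value is at most α₂ = α₁·k/m (Benjamini–Bogomolov).  Significant
variants are then thinned to an approximately independent subset by
greedy priority pruning on pairwise LD r².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix


def _pvalues(obj) -> np.ndarray:
    if isinstance(obj, pd.DataFrame):
        obj = obj["p"]
    p = np.asarray(obj, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in (0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} m·p_(j)/j, capped at 1.
    """
    p = _pvalues(pvalues)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def simes_p(region_stats) -> float:
    """Region-level Simes p: minimum BH-adjusted p within the region."""
    p = _pvalues(region_stats)
    if p.size == 0:
        raise ValueError("empty region")
    return float(bh_adjust(p).min())


@dataclass
class HierFDRResult:
    m: int
    alpha1: float
    simes: dict[str, float]
    region_q: dict[str, float]          # BH-adjusted Simes p across regions
    selected: list[str]
    k: int
    alpha2: float
    significant: dict[str, np.ndarray]  # region -> indices of significant variants

    def n_significant(self) -> int:
        return int(sum(len(v) for v in self.significant.values()))


def hierarchical_fdr(
    all_regions: Mapping[str, object], alpha1: float = 0.05
) -> HierFDRResult:
    """Two-level BH/Benjamini–Bogomolov correction over regions.

    ``all_regions`` maps a region name to its variant p-values (array or
    summary-statistics DataFrame with a ``p`` column).  Within selected
    regions, variants with within-region BH-adjusted p ≤ α₂ = α₁·k/m
    are significant; non-selected regions get empty sets.
    """
    if len(all_regions) == 0:
        raise ValueError("at least one region required")
    names = list(all_regions)
    pvecs = {name: _pvalues(all_regions[name]) for name in names}
    simes = {name: simes_p(pvecs[name]) for name in names}
    m = len(names)
    q = bh_adjust(np.array([simes[name] for name in names]))
    region_q = dict(zip(names, q))
    selected = [name for name in names if region_q[name] <= alpha1]
    k = len(selected)
    alpha2 = alpha1 * k / m
    significant: dict[str, np.ndarray] = {}
    for name in names:
        if name in selected:
            adj = bh_adjust(pvecs[name])
            significant[name] = np.flatnonzero(adj <= alpha2)
        else:
            significant[name] = np.array([], dtype=int)
    return HierFDRResult(
        m=m,
        alpha1=alpha1,
        simes=simes,
        region_q=region_q,
        selected=selected,
        k=k,
        alpha2=alpha2,
        significant=significant,
    )


def ld_r2(geno: GenotypeMatrix | np.ndarray, i: int | str, j: int | str) -> float:
    """Squared Pearson correlation between two dosage columns."""
    if isinstance(geno, GenotypeMatrix):
        if isinstance(i, str):
            i = geno.index_of(i)
        if isinstance(j, str):
            j = geno.index_of(j)
        dosages = geno.dosages
    else:
        dosages = np.asarray(geno, dtype=float)
    a, b = dosages[:, i], dosages[:, j]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance dosage column")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def priority_prune(
    stats_df: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_max: float = 0.1,
) -> pd.DataFrame:
    """Greedy LD pruning of significant variants by ascending p-value.

    Walks variants from smallest p (ties: larger |beta|, then id) and
    keeps each one iff its LD r² with every already-kept variant is
    below ``r2_max``.  The returned frame is ordered by p; all pairwise
    r² among kept variants are verified below the cap before returning.
    """
    if len(stats_df) == 0:
        return stats_df.copy()
    order = stats_df.assign(_abs_beta=-stats_df["beta"].abs()).sort_values(
        ["p", "_abs_beta", "variant_id"], kind="mergesort"
    )
    cols = {vid: geno.column(vid) for vid in order["variant_id"]}
    kept: list[str] = []
    for vid in order["variant_id"]:
        g = cols[vid]
        if all(np.corrcoef(g, cols[other])[0, 1] ** 2 < r2_max for other in kept):
            kept.append(vid)
    result = order[order["variant_id"].isin(kept)].drop(columns="_abs_beta")
    # post-hoc invariant: pruned set is in approximate linkage equilibrium
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            assert np.corrcoef(cols[kept[a]], cols[kept[b]])[0, 1] ** 2 < r2_max
    return result.reset_index(drop=True)
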