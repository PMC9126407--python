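"""Two-sample Mendelian randomization and mediation of causal chains.

Single-instrument MR with the ratio (Wald) estimator: the causal effect
of an exposure X on an outcome Y is β_IV = β_y / β_x, the
instrument-outcome effect divided by the instrument-exposure effect,
with the delta-method standard error truncated after the second term:

    se_IV = sqrt( se_y²/β_x² + β_y²·se_x²/β_x⁴ )

Instruments are lead variants passing the genome-wide threshold
p < 5×10⁻⁸; exposures whose lead misses the threshold are excluded.
For causal chains GE → PE → disease the indirect (mediated) effect is
the product of the two leg estimates with the product delta-method SE,
and complete mediation is declared when the total effect and the
indirect effect are both significant while their difference is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hfdr_ld import hierarchical_fdr
from .qtlscan import lead_variant

GENOME_WIDE_P = 5e-8


@dataclass
class MRResult:
    exposure_id: str
    outcome_id: str
    variant_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    beta_iv: float
    se_iv: float
    p: float
    p_adjusted: float | None = None


@dataclass
class CausalChain:
    """GE→PE→outcome mediation summary for one gene–tissue pair."""

    gene_id: str
    tissue: str
    beta_ge_pe: float
    se_ge_pe: float
    beta_pe_outcome: float
    se_pe_outcome: float
    indirect: float
    se_indirect: float
    total: float
    se_total: float
    diff: float
    diff_z: float
    diff_p: float
    total_p: float
    indirect_p: float
    complete: bool            # complete-mediation verdict
    incomplete_chain: bool = False


def select_instrument(stats_df: pd.DataFrame, p_max: float = GENOME_WIDE_P):
    """Lead variant if it passes the instrument threshold, else None."""
    lead = lead_variant(stats_df)
    if lead["p"] < p_max:
        return lead
    return None


def mr_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float) -> tuple[float, float, float]:
    """Ratio estimate, delta-method SE and normal two-sided p."""
    if beta_x == 0:
        raise ValueError("beta_x = 0: degenerate instrument")
    if se_x < 0 or se_y < 0:
        raise ValueError("standard errors must be non-negative")
    beta_iv = beta_y / beta_x
    se_iv = float(np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4))
    if se_iv > 0:
        p = float(np.clip(2.0 * stats.norm.sf(abs(beta_iv) / se_iv), np.finfo(float).tiny, 1.0))
    else:
        p = 0.0 if beta_iv != 0 else 1.0
    return beta_iv, se_iv, p


def _stat_at(stats_df: pd.DataFrame, variant_id: str, effect_allele: str) -> tuple[float, float]:
    """Beta/se of a variant in a stats table, harmonized to an allele."""
    rows = stats_df.loc[stats_df["variant_id"] == variant_id]
    if len(rows) == 0:
        raise KeyError(f"variant {variant_id!r} absent from outcome statistics")
    row = rows.iloc[0]
    beta, se = float(row["beta"]), float(row["se"])
    if row["effect_allele"] != effect_allele:
        beta = -beta
    return beta, se


def mr_single(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    p_max: float = GENOME_WIDE_P,
) -> MRResult | None:
    """Full single-instrument MR of one exposure on one outcome.

    Selects the instrument from the exposure statistics and looks its
    outcome association up in the outcome statistics (alleles
    harmonized).  Returns None when no instrument passes the threshold.
    """
    inst = select_instrument(exposure_stats, p_max)
    if inst is None:
        return None
    beta_y, se_y = _stat_at(outcome_stats, inst["variant_id"], inst["effect_allele"])
    beta_iv, se_iv, p = mr_ratio(float(inst["beta"]), float(inst["se"]), beta_y, se_y)
    return MRResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        variant_id=str(inst["variant_id"]),
        beta_x=float(inst["beta"]),
        se_x=float(inst["se"]),
        beta_y=beta_y,
        se_y=se_y,
        beta_iv=beta_iv,
        se_iv=se_iv,
        p=p,
    )


def mr_battery(
    exposure_stats: Mapping[str, pd.DataFrame],
    outcome_stats: pd.DataFrame,
    correction: str = "bonferroni",
    n_tests: int | None = None,
    groups: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    outcome_id: str = "outcome",
    p_max: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """MR of many exposures on one outcome with multiplicity control.

    ``correction='bonferroni'`` multiplies raw p-values by ``n_tests``
    (default: number of testable exposures).  ``correction='hierarchical'``
    applies the two-level FDR with ``groups`` mapping each exposure id
    to its family (e.g. gene, with tissues as the within-family level);
    the significance flag then reflects the family-then-member scheme
    and ``p_adjusted`` carries the within-family BH-adjusted p.
    """
    results: list[MRResult] = []
    for exp_id, stats_df in exposure_stats.items():
        res = mr_single(stats_df, outcome_stats, exp_id, outcome_id, p_max)
        if res is not None:
            results.append(res)
    if not results:
        return pd.DataFrame(
            columns=["exposure_id", "outcome_id", "variant_id", "beta_x", "se_x",
                     "beta_y", "se_y", "beta_iv", "se_iv", "p", "p_adjusted", "significant"]
        )
    frame = pd.DataFrame([r.__dict__ for r in results])
    if correction == "bonferroni":
        m = n_tests if n_tests is not None else len(frame)
        frame["p_adjusted"] = np.minimum(frame["p"] * m, 1.0)
        frame["significant"] = frame["p_adjusted"] <= alpha
    elif correction == "hierarchical":
        if groups is None:
            groups = {e: e for e in frame["exposure_id"]}
        frame["_family"] = frame["exposure_id"].map(groups)
        fam_p = {f: grp["p"].to_numpy() for f, grp in frame.groupby("_family", sort=True)}
        hres = hierarchical_fdr(fam_p, alpha1=alpha)
        frame["p_adjusted"] = np.nan
        frame["significant"] = False
        for fam, grp in frame.groupby("_family", sort=True):
            from .hfdr_ld import bh_adjust

            adj = bh_adjust(grp["p"].to_numpy())
            frame.loc[grp.index, "p_adjusted"] = adj
            sig_idx = hres.significant.get(fam, np.array([], dtype=int))
            frame.loc[grp.index[sig_idx], "significant"] = True
        frame = frame.drop(columns="_family")
    else:
        raise ValueError(f"unknown correction scheme {correction!r}")
    return frame


def mediation_chain(
    mr_ge_pe: MRResult | None,
    mr_pe_outcome: MRResult | None,
    mr_ge_outcome: MRResult | None,
    gene_id: str = "",
    tissue: str = "",
    alpha: float = 0.05,
) -> CausalChain:
    """Mediation summary of a GE → PE → outcome chain.

    indirect = β₁·β₂ with se = sqrt(β₁²·se₂² + β₂²·se₁²); the
    total-vs-indirect difference z treats the two estimates as
    independent (conservative).  A missing leg marks the chain
    incomplete without a verdict.
    """
    if mr_ge_pe is None or mr_pe_outcome is None or mr_ge_outcome is None:
        return CausalChain(
            gene_id=gene_id, tissue=tissue,
            beta_ge_pe=np.nan, se_ge_pe=np.nan,
            beta_pe_outcome=np.nan, se_pe_outcome=np.nan,
            indirect=np.nan, se_indirect=np.nan,
            total=np.nan, se_total=np.nan,
            diff=np.nan, diff_z=np.nan, diff_p=np.nan,
            total_p=np.nan, indirect_p=np.nan,
            complete=False, incomplete_chain=True,
        )
    b1, s1 = mr_ge_pe.beta_iv, mr_ge_pe.se_iv
    b2, s2 = mr_pe_outcome.beta_iv, mr_pe_outcome.se_iv
    indirect = b1 * b2
    se_ind = float(np.sqrt(b1**2 * s2**2 + b2**2 * s1**2))
    total, se_tot, total_p = mr_ge_outcome.beta_iv, mr_ge_outcome.se_iv, mr_ge_outcome.p
    if se_ind > 0:
        indirect_p = float(np.clip(2.0 * stats.norm.sf(abs(indirect) / se_ind),
                                   np.finfo(float).tiny, 1.0))
    else:
        indirect_p = 0.0 if indirect != 0 else 1.0
    diff = total - indirect
    denom = float(np.sqrt(se_tot**2 + se_ind**2))
    diff_z = diff / denom if denom > 0 else np.inf * np.sign(diff)
    diff_p = float(np.clip(2.0 * stats.norm.sf(abs(diff_z)), np.finfo(float).tiny, 1.0))
    complete = (total_p <= alpha) and (indirect_p <= alpha) and (diff_p > alpha)
    return CausalChain(
        gene_id=gene_id, tissue=tissue,
        beta_ge_pe=b1, se_ge_pe=s1,
        beta_pe_outcome=b2, se_pe_outcome=s2,
        indirect=indirect, se_indirect=se_ind,
        total=total, se_total=se_tot,
        diff=diff, diff_z=float(diff_z), diff_p=diff_p,
        total_p=total_p, indirect_p=indirect_p,
        complete=complete,
    )


def chains_frame(chains: list[CausalChain]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in chains])
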