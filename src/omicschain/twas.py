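"""Predicted-expression association (summary-statistics TWAS).

Associates the genetically regulated component of gene expression (gGE)
with a downstream trait.  Two equivalent routes are provided:

- ``predict_expression`` builds per-sample gGE from dosages and a
  per-gene variant weight model, for individual-level regression;
- ``summary_twas`` computes the same association z-score from the
  trait's per-variant summary statistics plus an LD reference panel,
  in the S-PrediXcan/MetaXcan style:

      z_gene = Σ_l w_l (σ_l / σ_g) (β_l / se_l)

  with σ_l² the panel dosage variance of variant l and
  σ_g² = wᵀ Γ w the variance of the weighted score under the panel
  covariance Γ.  The reported effect is per unit of predicted
  expression: effect = Σ_l w_l σ_l² β_l / σ_g².

Multiple-testing control across tissues and genes reuses the
hierarchical FDR machinery with tissues as the within-family level and
genes/proteins as families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hfdr_ld import HierFDRResult, hierarchical_fdr
from .simdata import GenotypeMatrix


@dataclass
class WeightModel:
    """Per-gene, per-tissue variant weights (effect-allele oriented)."""

    gene_id: str
    tissue: str
    weights: pd.DataFrame  # columns: variant_id, effect_allele, weight

    def __post_init__(self):
        w = self.weights["weight"].to_numpy(dtype=float)
        if len(w) == 0 or not np.any(w != 0):
            raise ValueError(f"{self.gene_id}/{self.tissue}: model has no non-zero weight")


@dataclass
class TwasResult:
    gene_id: str
    tissue: str
    z: float
    effect: float
    p: float
    n_variants_used: int


def predict_expression(geno: GenotypeMatrix, model: WeightModel) -> np.ndarray:
    """Per-sample predicted expression gGE = Σ_l w_l · dosage_l.

    Model variants absent from the genotype matrix are dropped (their
    count is recorded on the returned array's ``dropped`` attribute via
    a companion return is avoided; a ValueError is raised when nothing
    usable remains).
    """
    ids = geno.variants["variant_id"].to_numpy()
    pos = {v: i for i, v in enumerate(ids)}
    cols, w = [], []
    for _, row in model.weights.iterrows():
        if row["variant_id"] in pos:
            cols.append(pos[row["variant_id"]])
            w.append(float(row["weight"]))
    if not cols:
        raise ValueError(f"{model.gene_id}/{model.tissue}: no model variant found in genotypes")
    return geno.dosages[:, cols] @ np.asarray(w)


def summary_twas(
    pe_stats: pd.DataFrame,
    model: WeightModel,
    ld_ref: GenotypeMatrix,
) -> TwasResult:
    """Summary-statistics association of predicted expression with a trait.

    ``pe_stats`` must carry per-variant beta/se of the trait; effect
    alleles are harmonized against the model (mismatched alleles flip
    the weight sign).  The LD panel supplies σ_l and Γ.
    """
    stats_by_id = pe_stats.set_index("variant_id")
    ids = ld_ref.variants["variant_id"].to_numpy()
    panel_pos = {v: i for i, v in enumerate(ids)}

    used_cols, w_list, beta_list, se_list = [], [], [], []
    for _, row in model.weights.iterrows():
        vid = row["variant_id"]
        if vid not in panel_pos or vid not in stats_by_id.index:
            continue
        srow = stats_by_id.loc[vid]
        beta_l = float(srow["beta"])
        if srow["effect_allele"] != row["effect_allele"]:
            beta_l = -beta_l  # re-orient the stats to the model's allele
        used_cols.append(panel_pos[vid])
        w_list.append(float(row["weight"]))
        beta_list.append(beta_l)
        se_list.append(float(srow["se"]))
    if not used_cols:
        raise ValueError(f"{model.gene_id}/{model.tissue}: no usable variants")

    w = np.asarray(w_list)
    beta = np.asarray(beta_list)
    se = np.asarray(se_list)
    D = ld_ref.dosages[:, used_cols]
    gamma = np.cov(D, rowvar=False, ddof=1)
    gamma = np.atleast_2d(gamma)
    sigma_l = np.sqrt(np.diag(gamma))
    sigma_g2 = float(w @ gamma @ w)
    if sigma_g2 <= 0:
        raise ValueError("degenerate LD panel: predicted expression has no variance")
    sigma_g = np.sqrt(sigma_g2)

    z = float(np.sum(w * (sigma_l / sigma_g) * (beta / se)))
    effect = float(np.sum(w * sigma_l**2 * beta) / sigma_g2)
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0))
    return TwasResult(
        gene_id=model.gene_id,
        tissue=model.tissue,
        z=z,
        effect=effect,
        p=p,
        n_variants_used=len(used_cols),
    )


def results_frame(results: list[TwasResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "tissue": r.tissue,
                "z": r.z,
                "effect": r.effect,
                "p": r.p,
                "n_variants_used": r.n_variants_used,
            }
            for r in results
        ]
    )


def hierarchical_fdr_tissues(
    results: list[TwasResult] | pd.DataFrame, alpha1: float = 0.05
) -> tuple[pd.DataFrame, HierFDRResult]:
    """Two-level FDR with tissues within each gene/protein family.

    Returns the significant (gene, tissue) pairs and the underlying
    hierarchical-FDR result keyed by gene.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_frame(results)
    if len(frame) == 0:
        raise ValueError("no TWAS results")
    by_gene = {
        gene: grp.reset_index(drop=True) for gene, grp in frame.groupby("gene_id", sort=True)
    }
    hres = hierarchical_fdr({g: grp["p"].to_numpy() for g, grp in by_gene.items()}, alpha1)
    rows = []
    for gene, idx in hres.significant.items():
        grp = by_gene[gene]
        for i in idx:
            rows.append(grp.iloc[int(i)])
    sig = pd.DataFrame(rows).reset_index(drop=True) if rows else frame.iloc[0:0].copy()
    return sig, hres
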