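"""Effect-direction concordance, sex-difference tests and correlation checks.

Utilities for comparing a protein QTL's effect direction against the
same variant's expression QTL effects across tissues, for contrasting
sex-stratified effect estimates, and for validating transcript–protein
relationships with Pearson partial correlation.  Also builds the
three-way overlap report between analysis strategies (predicted-
expression association, MR, and QTL direction discordance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DirectionSummary:
    gene_id: str
    n_tissues_significant: int
    n_discordant: int
    fraction_discordant: float
    verdict: str  # predominantly_discordant | mixed | concordant
    n_excluded_zero: int = 0


def direction_classify(
    pqtl_beta: float,
    eqtl_betas,
    significant=None,
    gene_id: str = "",
    threshold: float = 0.75,
) -> DirectionSummary:
    """Classify pQTL-vs-eQTL direction consistency across tissues.

    A significant tissue is discordant when the sign of its eQTL beta is
    opposite to the pQTL beta.  The verdict is
    ``predominantly_discordant`` when the discordant fraction strictly
    exceeds ``threshold`` (strict: 3 of 4 tissues is exactly 0.75 and
    counts as ``mixed``), ``concordant`` when no tissue is discordant,
    and ``mixed`` otherwise.  Zero betas are excluded from the counts.

    ``significant`` may be a boolean mask or per-tissue p-values
    (significant at p ≤ 0.05); ``None`` treats every tissue as
    significant.
    """
    eqtl_betas = np.asarray(eqtl_betas, dtype=float)
    if significant is None:
        sig = np.ones(len(eqtl_betas), dtype=bool)
    else:
        significant = np.asarray(significant)
        sig = significant if significant.dtype == bool else significant <= 0.05
    nonzero = eqtl_betas != 0
    n_excluded = int((sig & ~nonzero).sum())
    use = sig & nonzero
    n_sig = int(use.sum())
    if n_sig == 0:
        raise ValueError(f"{gene_id or 'gene'}: no significant tissue with non-zero beta")
    discordant = np.sign(eqtl_betas[use]) * np.sign(pqtl_beta) < 0
    n_disc = int(discordant.sum())
    fraction = n_disc / n_sig
    if fraction > threshold:
        verdict = "predominantly_discordant"
    elif n_disc == 0:
        verdict = "concordant"
    else:
        verdict = "mixed"
    return DirectionSummary(
        gene_id=gene_id,
        n_tissues_significant=n_sig,
        n_discordant=n_disc,
        fraction_discordant=fraction,
        verdict=verdict,
        n_excluded_zero=n_excluded,
    )


def sex_difference_test(beta_f: float, se_f: float, beta_m: float, se_m: float) -> tuple[float, float]:
    """t-test of equal effect sizes between female and male strata.

    t = (β_f − β_m) / sqrt(se_f² + se_m²), two-sided p from the
    standard normal reference.
    """
    if se_f <= 0 or se_m <= 0:
        raise ValueError("standard errors must be positive")
    t = (beta_f - beta_m) / np.sqrt(se_f**2 + se_m**2)
    p = float(2.0 * stats.norm.sf(abs(t)))
    return float(t), p


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson partial correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept)
    and the residuals' Pearson correlation is returned with a two-sided
    p-value from the t reference on n − k − 2 degrees of freedom
    (k covariates).  With no covariates this is the plain Pearson
    correlation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} observations for {k} covariates")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    Q, _ = np.linalg.qr(X)
    xr = x - Q @ (Q.T @ x)
    yr = y - Q @ (Q.T @ y)
    r = float(xr @ yr / np.sqrt((xr @ xr) * (yr @ yr)))
    df = n - k - 2
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def overlap_sets(set_a, set_b, set_c, labels=("mx_negative", "mr_negative", "qtl_discordant")) -> dict:
    """Three-way overlap report between gene sets.

    Returns all seven exclusive intersection cells plus the central
    (triple) intersection as a sorted list under ``center``.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    la, lb, lc = labels
    center = a & b & c
    report = {
        f"{la}_only": sorted(a - b - c),
        f"{lb}_only": sorted(b - a - c),
        f"{lc}_only": sorted(c - a - b),
        f"{la}_{lb}": sorted((a & b) - c),
        f"{la}_{lc}": sorted((a & c) - b),
        f"{lb}_{lc}": sorted((b & c) - a),
        f"{la}_{lb}_{lc}": sorted(center),
        "center": sorted(center),
    }
    return report
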