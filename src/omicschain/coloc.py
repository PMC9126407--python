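"""Bayesian co-localization of two association signals in one region.

Given summary statistics of two traits over a shared set of variants,
evaluates the five standard hypotheses under the one-causal-variant
assumption:

- H0: no association with either trait
- H1/H2: association with trait 1 / trait 2 only
- H3: both traits associated, two distinct causal variants
- H4: both traits associated, one shared causal variant

Per-variant evidence is the Wakefield approximate Bayes factor computed
from the effect estimate and its standard error; hypothesis posteriors
are accumulated in log space (log-sum-exp) so small probabilities never
underflow.  The verdict uses the conventional ≥ 0.75 posterior
thresholds: ``shared`` when PP4 ≥ 0.75, ``independent`` when
PP3 ≥ 0.75, otherwise ``undecided``.  Co-localization is judged
regardless of effect direction: negating all betas of one trait leaves
every posterior unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities and prior effect variances.

    ``p1``/``p2`` are priors of association with trait 1/2 only, ``p12``
    of association with both; ``w1``/``w2`` are the prior variances of
    the true effect (0.15² is the conventional quantitative-trait
    choice; 0.2² is typical for binary traits on the log-odds scale).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.15**2
    w2: float = 0.15**2

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be positive")


@dataclass
class ColocResult:
    pp: np.ndarray          # posterior probabilities PP0..PP4
    n_variants: int
    n_flipped: int = 0
    n_dropped: int = 0
    threshold: float = 0.75

    def __post_init__(self):
        total = float(self.pp.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def pp0(self) -> float: return float(self.pp[0])
    @property
    def pp1(self) -> float: return float(self.pp[1])
    @property
    def pp2(self) -> float: return float(self.pp[2])
    @property
    def pp3(self) -> float: return float(self.pp[3])
    @property
    def pp4(self) -> float: return float(self.pp[4])

    @property
    def verdict(self) -> str:
        if self.pp4 >= self.threshold:
            return "shared"
        if self.pp3 >= self.threshold:
            return "independent"
        return "undecided"


def log_abf(beta, se, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor of association vs null.

    With z = beta/se, V = se² and shrinkage r = w/(V + w):
    ``log ABF = 0.5·log(1 − r) + 0.5·z²·r``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if w <= 0:
        raise ValueError("prior variance w must be positive")
    v = se**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def harmonize(
    stats1: pd.DataFrame, stats2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, int, int]:
    """Align two summary-statistics frames on shared variants.

    Joins on ``variant_id``; where effect alleles disagree, the second
    trait's beta is sign-flipped (and EAF complemented) if its alleles
    are simply swapped relative to trait 1, otherwise the variant is
    dropped.  Returns the aligned frames plus flip and drop counts.
    """
    merged = stats1.merge(
        stats2, on="variant_id", suffixes=("_1", "_2"), how="inner"
    )
    same = merged["effect_allele_1"] == merged["effect_allele_2"]
    if "other_allele_1" in merged and "other_allele_2" in merged:
        swapped = (~same) & (merged["effect_allele_2"] == merged["other_allele_1"]) & (
            merged["effect_allele_1"] == merged["other_allele_2"]
        )
    else:
        # without the other allele any mismatch is treated as a swap
        swapped = ~same
    keep = same | swapped
    n_dropped = int((~keep).sum())
    merged = merged.loc[keep].reset_index(drop=True)
    flip = swapped.loc[keep].to_numpy()
    n_flipped = int(flip.sum())

    def side(suffix: str, flip_this: np.ndarray) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "variant_id": merged["variant_id"],
                "effect_allele": merged["effect_allele_1"],
                "beta": merged[f"beta{suffix}"].to_numpy(),
                "se": merged[f"se{suffix}"].to_numpy(),
            }
        )
        if f"eaf{suffix}" in merged:
            out["eaf"] = merged[f"eaf{suffix}"].to_numpy()
        out.loc[flip_this, "beta"] *= -1.0
        if "eaf" in out:
            out.loc[flip_this, "eaf"] = 1.0 - out.loc[flip_this, "eaf"]
        return out

    return side("_1", np.zeros(len(merged), bool)), side("_2", flip), n_flipped, n_dropped


def colocalize(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    priors: ColocPriors | None = None,
    threshold: float = 0.75,
) -> ColocResult:
    """Posterior probabilities of H0–H4 for one region.

    Inputs are per-variant summary statistics of the two traits; they
    are harmonized on the intersection of variant ids with effect-allele
    flipping.  All hypothesis sums run in log space.
    """
    if priors is None:
        priors = ColocPriors()
    s1, s2, n_flipped, n_dropped = harmonize(stats1, stats2)
    if len(s1) == 0:
        raise ValueError("no shared variants between the two traits")

    l1 = log_abf(s1["beta"].to_numpy(), s1["se"].to_numpy(), priors.w1)
    l2 = log_abf(s2["beta"].to_numpy(), s2["se"].to_numpy(), priors.w2)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(priors.p1) + lsum1
    lh2 = np.log(priors.p2) + lsum2
    lh4 = np.log(priors.p12) + lsum12
    # H3: sum over ordered pairs of distinct variants = S1*S2 - S12
    both = lsum1 + lsum2
    if len(s1) < 2 or lsum12 >= both:
        lh3 = -np.inf
    else:
        lh3 = np.log(priors.p1) + np.log(priors.p2) + both + np.log1p(-np.exp(lsum12 - both))

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(logs - logsumexp(logs))
    pp /= pp.sum()
    return ColocResult(
        pp=pp,
        n_variants=len(s1),
        n_flipped=n_flipped,
        n_dropped=n_dropped,
        threshold=threshold,
    )
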