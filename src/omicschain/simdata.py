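"""Synthetic multi-omics cohorts with known causal architecture.

This module generates the ground-truth test bed for the whole analysis
chain: LD-structured genotypes, tissue-specific gene expression (GE),
blood protein expression (PE), age/sex covariates and a binary disease
outcome whose genetic risk is routed (partly or fully) through PE.

Each simulated *region* plays the role of one gene / protein pair.  A
region is assigned one of three causal architectures:

``shared``
    GE and PE are driven by the same causal variant — the situation a
    co-localization analysis should call H4.
``independent``
    GE and PE are driven by two distinct variants in low LD (H3).
``null``
    no genetic effect on either molecular layer.

The per-region ``sign_pattern`` controls whether the PE effect of the
causal variant has the same (``concordant``) or the opposite
(``discordant``) sign as the GE effects, emulating protein/transcript
pairs whose QTL effect directions disagree.

Genotypes are built from first-order autoregressive latent-Gaussian
haplotypes: for each haplotype a latent AR(1) series is thresholded at
the quantile of the target allele frequency, and two haplotypes are
summed into a dosage in {0, 1, 2}.  Correlation between adjacent
variants therefore decays geometrically with ``ld_decay``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

ARCHITECTURES = ("shared", "independent", "null")
SIGN_PATTERNS = ("concordant", "discordant")

# stage offsets mixed into the seed so every operation has its own stream
_STREAM_GENO = 1
_STREAM_TRUTH = 2
_STREAM_OMICS = 3
_STREAM_OUTCOME = 4
_STREAM_SPLIT = 5


class ConfigError(ValueError):
    """Raised for invalid simulation configuration values."""


def _as_region_list(value, n_regions: int, allowed: tuple, name: str) -> list[str]:
    if isinstance(value, str):
        value = [value] * n_regions
    value = list(value)
    if len(value) != n_regions:
        raise ConfigError(f"{name} must have one entry per region ({n_regions}), got {len(value)}")
    for v in value:
        if v not in allowed:
            raise ConfigError(f"invalid {name} entry {v!r}; allowed: {allowed}")
    return value


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    n_samples
        Number of individuals.
    n_variants_per_region, n_regions
        Cis-region geometry; each region models one gene/protein pair
        on its own chromosome.
    n_tissues
        Number of parallel GE compartments; tissue 0 is the
        blood-like compartment that may feed PE via
        ``pathway_coupling``.
    maf_range
        Minor-allele-frequency bounds, drawn uniformly per variant.
    ld_decay
        AR(1) autocorrelation of the latent haplotype process in
        ``[0, 1)``; 0 gives linkage equilibrium.
    architectures, sign_patterns
        Either a single string applied to every region or one entry per
        region (see module docstring).
    ge_h2
        Target cis-heritability of GE in each tissue.
    pe_h2
        Target cis-heritability of the *direct* genetic PE effect
        (set 0 to route all PE genetics through the GE coupling).
    pathway_coupling
        Loading of PE on blood GE (the free GE→PE coupling δ).
    sex_interaction
        Multiplier applied to male genetic effects on GE and PE
        (1 = no sexual dimorphism).
    age_effect_pe, sex_effect_pe
        Covariate effects on PE, in PE residual-SD units per SD of age
        and for male vs female respectively.
    theta_pe
        Log-odds of the outcome per unit PE.
    mediation_fraction
        Fraction of the genetic GE→outcome effect routed through PE;
        1 means no direct GE→outcome term.
    theta_ge_direct
        Direct GE→outcome log-odds used only when
        ``mediation_fraction == 0`` (otherwise the direct term is
        derived from ``mediation_fraction``).
    prevalence
        Marginal outcome prevalence; the intercept is solved for it.
    independent_r2_cap
        Maximum LD r² allowed between the GE and PE causal variants of
        an ``independent`` region.
    """

    n_samples: int = 2000
    n_variants_per_region: int = 50
    n_regions: int = 5
    n_tissues: int = 3
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.9
    architectures: Sequence[str] | str = "shared"
    sign_patterns: Sequence[str] | str = "concordant"
    ge_h2: float = 0.1
    pe_h2: float = 0.1
    pathway_coupling: float = 0.0
    sex_interaction: float = 1.0
    age_range: tuple[float, float] = (40.0, 80.0)
    age_effect_pe: float = 0.1
    sex_effect_pe: float = 0.2
    theta_pe: float = 0.5
    mediation_fraction: float = 1.0
    theta_ge_direct: float = 0.3
    prevalence: float = 0.3
    independent_r2_cap: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0.01 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ConfigError(f"ld_decay must be in [0, 1), got {self.ld_decay}")
        if self.n_variants_per_region < 2:
            raise ConfigError("n_variants_per_region must be >= 2")
        if not (0.0 <= self.mediation_fraction <= 1.0):
            raise ConfigError("mediation_fraction must be in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not (0.0 <= self.ge_h2 < 1.0) or not (0.0 <= self.pe_h2 < 1.0):
            raise ConfigError("heritabilities must be in [0, 1)")
        # validate per-region settings eagerly so errors surface at construction
        self.region_architectures()
        self.region_sign_patterns()

    def region_architectures(self) -> list[str]:
        return _as_region_list(self.architectures, self.n_regions, ARCHITECTURES, "architectures")

    def region_sign_patterns(self) -> list[str]:
        return _as_region_list(self.sign_patterns, self.n_regions, SIGN_PATTERNS, "sign_patterns")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GenotypeMatrix:
    """Samples × variants allele-dosage matrix with variant metadata.

    ``dosages`` holds counts of the effect allele in {0, 1, 2};
    ``variants`` is a DataFrame with columns ``variant_id, chrom, pos,
    region, effect_allele, other_allele, maf`` (declared MAF).
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self):
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns and variant metadata rows differ")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_eaf(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.index_of(variant_id)
        return self.dosages[:, idx]

    def index_of(self, variant_id: str) -> int:
        matches = np.flatnonzero(self.variants["variant_id"].to_numpy() == variant_id)
        if len(matches) == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return int(matches[0])

    def region_indices(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.variants["region"].to_numpy() == region)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx], self.variants.copy())


@dataclass
class RegionTruth:
    region: int
    architecture: str
    sign_pattern: str
    ge_causal: int | None          # column index into the full dosage matrix
    pe_causal: int | None
    beta_ge: np.ndarray            # per-tissue GE effect (female-reference scale)
    gamma_pe: float                # direct genetic PE effect


@dataclass
class TruthTable:
    """Ground truth of the generative model, for parameter-recovery tests."""

    regions: list[RegionTruth]
    theta_pe: float
    theta_ge_direct: float
    pathway_coupling: float

    def region(self, r: int) -> RegionTruth:
        return self.regions[r]

    def true_indirect_effect(self, r: int) -> float:
        """Genetic-scale indirect GE→outcome effect through PE for region r."""
        return self.theta_pe * self.pathway_coupling

    def true_total_effect(self, r: int) -> float:
        return self.true_indirect_effect(r) + self.theta_ge_direct

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rt in self.regions:
            rows.append(
                {
                    "region": rt.region,
                    "architecture": rt.architecture,
                    "sign_pattern": rt.sign_pattern,
                    "ge_causal": -1 if rt.ge_causal is None else rt.ge_causal,
                    "pe_causal": -1 if rt.pe_causal is None else rt.pe_causal,
                    "gamma_pe": rt.gamma_pe,
                    **{f"beta_ge_t{t}": b for t, b in enumerate(rt.beta_ge)},
                }
            )
        return pd.DataFrame(rows)


@dataclass
class OmicsData:
    """Molecular layers and covariates of one simulated cohort.

    ``ge`` has shape (n_regions, n_tissues, n_samples); ``pe`` has shape
    (n_regions, n_samples); ``covariates`` holds ``age`` and ``sex``
    (0 = female, 1 = male).
    """

    ge: np.ndarray
    pe: np.ndarray
    covariates: pd.DataFrame

    @property
    def sex(self) -> np.ndarray:
        return self.covariates["sex"].to_numpy()


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw LD-structured dosages from AR(1) latent-Gaussian haplotypes.

    Within a region the latent process of each haplotype follows
    ``z_j = ld_decay * z_{j-1} + sqrt(1 - ld_decay^2) * e_j`` and the
    allele indicator is ``z_j < Phi^{-1}(maf_j)``, so every variant's
    allele frequency equals its declared MAF and the latent correlation
    between variants i < j is ``ld_decay^(j-i)``.  Two haplotypes per
    sample are summed into the dosage.  Deterministic given the seed.
    """
    rng = config.rng(_STREAM_GENO)
    n, m, R = config.n_samples, config.n_variants_per_region, config.n_regions
    rho = config.ld_decay
    blocks, meta = [], []
    for r in range(R):
        mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
        thresholds = stats.norm.ppf(mafs)
        z = np.empty((2 * n, m))
        z[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, m - 1))
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j - 1]
        alleles = (z < thresholds).astype(np.int8)
        dos = alleles[:n] + alleles[n:]
        blocks.append(dos.astype(np.float64))
        chrom = f"chr{r + 1}"
        positions = 1_000_000 + 2_000 * np.arange(m)
        for j in range(m):
            meta.append(
                {
                    "variant_id": f"{chrom}_{positions[j]}",
                    "chrom": chrom,
                    "pos": int(positions[j]),
                    "region": r,
                    "effect_allele": "A",
                    "other_allele": "G",
                    "maf": mafs[j],
                }
            )
    return GenotypeMatrix(np.concatenate(blocks, axis=1), pd.DataFrame(meta))


def _scaled_beta(h2: float, dosage: np.ndarray) -> float:
    """Effect size giving cis-heritability h2 with unit residual variance."""
    if h2 == 0.0:
        return 0.0
    var_g = dosage.var()
    return float(np.sqrt(h2 / (1.0 - h2) / var_g))


def make_truth(geno: GenotypeMatrix, config: SimConfig) -> TruthTable:
    """Assign causal variants and effect sizes per region.

    Shared regions reuse the GE causal variant for PE; independent
    regions pick a PE causal variant whose empirical LD r² with the GE
    variant is below ``independent_r2_cap``.  Null regions carry no
    effects.
    """
    rng = config.rng(_STREAM_TRUTH)
    archs = config.region_architectures()
    signs = config.region_sign_patterns()
    regions: list[RegionTruth] = []
    for r in range(config.n_regions):
        cols = geno.region_indices(r)
        arch, sign = archs[r], signs[r]
        if arch == "null":
            regions.append(
                RegionTruth(r, arch, sign, None, None, np.zeros(config.n_tissues), 0.0)
            )
            continue
        ge_causal = int(rng.choice(cols))
        if arch == "shared":
            pe_causal = ge_causal
        else:
            g = geno.dosages[:, ge_causal]
            r2 = np.array(
                [np.corrcoef(g, geno.dosages[:, c])[0, 1] ** 2 for c in cols]
            )
            candidates = cols[(r2 < config.independent_r2_cap) & (cols != ge_causal)]
            if len(candidates) == 0:
                raise ConfigError(
                    f"region {r}: no variant with r2 < {config.independent_r2_cap} "
                    "available for an independent architecture; "
                    "increase region size or lower ld_decay"
                )
            pe_causal = int(rng.choice(candidates))
        beta = _scaled_beta(config.ge_h2, geno.dosages[:, ge_causal])
        beta_ge = np.full(config.n_tissues, beta)
        gamma = _scaled_beta(config.pe_h2, geno.dosages[:, pe_causal])
        if sign == "discordant":
            gamma = -gamma
        regions.append(RegionTruth(r, arch, sign, ge_causal, pe_causal, beta_ge, gamma))
    return TruthTable(
        regions=regions,
        theta_pe=config.theta_pe,
        theta_ge_direct=_direct_outcome_effect(config),
        pathway_coupling=config.pathway_coupling,
    )


def _direct_outcome_effect(config: SimConfig) -> float:
    f = config.mediation_fraction
    if f == 1.0:
        return 0.0
    if f == 0.0:
        return config.theta_ge_direct
    # indirect/(indirect + direct) = f  =>  direct = indirect*(1/f - 1)
    indirect = config.theta_pe * config.pathway_coupling
    return indirect * (1.0 / f - 1.0)


def simulate_omics(
    geno: GenotypeMatrix, truth: TruthTable, config: SimConfig
) -> OmicsData:
    """Simulate tissue GE, blood PE and covariates on top of genotypes.

    GE in tissue t: ``beta_t(sex) * G_causal + N(0, 1)``.  PE:
    ``gamma(sex) * G_causal(PE) + delta * GE_blood + age and sex
    effects + N(0, 1)`` where the blood compartment is tissue 0 and
    male effects are scaled by ``sex_interaction``.
    """
    if truth.regions and any(
        rt.ge_causal is not None and rt.ge_causal >= geno.n_variants for rt in truth.regions
    ):
        raise ValueError("truth table refers to variants outside the genotype matrix")
    rng = config.rng(_STREAM_OMICS)
    n = geno.n_samples
    sex = rng.integers(0, 2, size=n)  # Bernoulli(0.5); 1 = male
    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    age_std = (age - age.mean()) / age.std()
    sex_scale = np.where(sex == 1, config.sex_interaction, 1.0)

    R, T = config.n_regions, config.n_tissues
    ge = np.empty((R, T, n))
    pe = np.empty((R, n))
    for rt in truth.regions:
        r = rt.region
        g_ge = geno.dosages[:, rt.ge_causal] if rt.ge_causal is not None else 0.0
        g_pe = geno.dosages[:, rt.pe_causal] if rt.pe_causal is not None else 0.0
        for t in range(T):
            ge[r, t] = rt.beta_ge[t] * sex_scale * g_ge + rng.standard_normal(n)
        pe[r] = (
            rt.gamma_pe * sex_scale * g_pe
            + config.pathway_coupling * ge[r, 0]
            + config.age_effect_pe * age_std
            + config.sex_effect_pe * sex
            + rng.standard_normal(n)
        )
    covariates = pd.DataFrame({"age": age, "sex": sex})
    return OmicsData(ge=ge, pe=pe, covariates=covariates)


def simulate_outcome(
    pe: np.ndarray,
    ge: np.ndarray,
    truth: TruthTable,
    config: SimConfig,
    outcome_regions: Sequence[int] | None = None,
) -> np.ndarray:
    """Draw a binary outcome from a logistic model on PE and blood GE.

    ``logit P(Y=1) = alpha + sum_r (theta_pe * PE_r + theta_direct *
    GE_r,blood)`` over the contributing regions (all non-null regions by
    default).  The intercept is solved so the sample-average risk equals
    the configured prevalence.  ``theta_direct`` is 0 when
    ``mediation_fraction == 1``.
    """
    if not (0.0 < config.prevalence < 1.0):
        raise ConfigError("prevalence must be in (0, 1)")
    if outcome_regions is None:
        outcome_regions = [rt.region for rt in truth.regions if rt.architecture != "null"]
    n = pe.shape[-1]
    lin = np.zeros(n)
    for r in outcome_regions:
        lin += truth.theta_pe * pe[r] + truth.theta_ge_direct * ge[r, 0]

    def mean_risk(alpha: float) -> float:
        return float(special.expit(alpha + lin).mean()) - config.prevalence

    alpha = optimize.brentq(mean_risk, -50.0, 50.0)
    rng = config.rng(_STREAM_OUTCOME)
    return (rng.random(n) < special.expit(alpha + lin)).astype(np.int8)


def make_split(n_samples: int, sizes: Sequence[int], seed: int = 0) -> tuple[np.ndarray, ...]:
    """Partition sample indices into disjoint subsets of the given sizes."""
    sizes = [int(s) for s in sizes]
    if any(s <= 0 for s in sizes):
        raise ConfigError("split sizes must be positive")
    if sum(sizes) > n_samples:
        raise ConfigError(
            f"requested split sizes {sizes} exceed n_samples={n_samples}"
        )
    perm = np.random.default_rng([int(seed), _STREAM_SPLIT]).permutation(n_samples)
    out, start = [], 0
    for s in sizes:
        out.append(np.sort(perm[start : start + s]))
        start += s
    return tuple(out)


def make_two_sample_split(
    n_samples: int,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping exposure/outcome index sets for two-sample MR.

    Defaults to an even split.  Summary statistics computed on the two
    sets are then independent, emulating a two-cohort design.
    """
    if n_exposure is None:
        n_exposure = n_samples // 2
    if n_outcome is None:
        n_outcome = n_samples - n_exposure
    a, b = make_split(n_samples, [n_exposure, n_outcome], seed=seed)
    return a, b
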