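import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One shared-architecture cohort reused across read-only tests."""
    from omicschain.simdata import (
        SimConfig,
        make_truth,
        simulate_genotypes,
        simulate_omics,
    )

    cfg = SimConfig(
        n_samples=1500,
        n_variants_per_region=30,
        n_regions=3,
        n_tissues=2,
        architectures=("shared", "independent", "null"),
        sign_patterns=("discordant", "concordant", "concordant"),
        ld_decay=0.8,
        maf_range=(0.1, 0.5),
        ge_h2=0.15,
        pe_h2=0.15,
        seed=42,
    )
    geno = simulate_genotypes(cfg)
    truth = make_truth(geno, cfg)
    omics = simulate_omics(geno, truth, cfg)
    return cfg, geno, truth, omics


def make_stats(p, beta=None, ids=None, effect_allele="A"):
    """Tiny summary-statistics frame for unit tests."""
    p = np.asarray(p, dtype=float)
    if beta is None:
        beta = np.ones_like(p)
    if ids is None:
        ids = [f"v{i}" for i in range(len(p))]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": effect_allele,
            "eaf": 0.3,
            "beta": np.asarray(beta, dtype=float),
            "se": 0.1,
            "p": p,
            "n": 1000,
            "stratum": "combined",
        }
    )


@pytest.fixture
def stats_factory():
    return make_stats
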