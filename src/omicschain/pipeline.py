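"""End-to-end orchestration of the multi-omics causal-chain analysis.

``run_all`` executes the full study design on one synthetic cohort:

1. simulate genotypes, tissue GE, blood PE, covariates and disease;
2. cis-region association scans (PE combined + sex strata, GE per
   tissue) on disjoint sample subsets emulating separate cohorts;
3. hierarchical FDR over protein regions, lead pQTLs, LD pruning;
4. co-localization of GE and PE signals per selected gene × tissue;
5. summary-statistics TWAS of predicted expression against PE with
   tissue-within-gene hierarchical FDR;
6. MR of GE on PE (hierarchical correction), of PE on disease
   (Bonferroni), and GE→PE→disease mediation chains;
7. direction-concordance classification and the three-way overlap of
   negative-relation gene sets.

Sample subsets: the cohort is split four ways — GE statistics, PE
statistics (discovery + GE→PE outcome leg), a second PE subset for the
PE→disease exposure leg, and the disease subset — so that every MR leg
rests on independent samples and the mediated (indirect) estimate does
not collapse algebraically onto the total.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import direction_classify, overlap_sets, sex_difference_test
from .coloc import ColocPriors, colocalize
from .hfdr_ld import HierFDRResult, hierarchical_fdr, priority_prune
from .mr_mediation import (
    CausalChain,
    MRResult,
    chains_frame,
    mediation_chain,
    mr_ratio,
    select_instrument,
)
from .qtlscan import lead_variant, scan_region
from .simdata import (
    GenotypeMatrix,
    SimConfig,
    make_split,
    make_truth,
    simulate_genotypes,
    simulate_omics,
    simulate_outcome,
)
from .twas import WeightModel, hierarchical_fdr_tissues, results_frame, summary_twas


@dataclass(frozen=True)
class PipelineConfig:
    """One config block holding the simulation and every threshold."""

    sim: SimConfig = field(default_factory=SimConfig)
    split_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha1: float = 0.05
    r2_max: float = 0.1
    pp_threshold: float = 0.75
    instrument_p_max: float = 5e-8
    discordance_threshold: float = 0.75
    eqtl_alpha: float = 0.05
    chain_alpha: float = 0.05
    sex_stratified: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["maf_range"] = list(self.sim.maf_range)
        d["sim"]["age_range"] = list(self.sim.age_range)
        if not isinstance(d["sim"]["architectures"], str):
            d["sim"]["architectures"] = list(d["sim"]["architectures"])
        if not isinstance(d["sim"]["sign_patterns"], str):
            d["sim"]["sign_patterns"] = list(d["sim"]["sign_patterns"])
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        sim = dict(sim)
        for key in ("maf_range", "age_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "architectures" in sim and not isinstance(sim["architectures"], str):
            sim["architectures"] = tuple(sim["architectures"])
        if "sign_patterns" in sim and not isinstance(sim["sign_patterns"], str):
            sim["sign_patterns"] = tuple(sim["sign_patterns"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(sim=SimConfig(**sim), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Machine-readable result of one end-to-end run."""

    config_hash: str
    seed: int
    version: str
    n_samples: int
    n_regions: int
    n_variants: int
    simes: dict[str, float]
    k: int
    alpha2: float
    n_significant_variants: int
    n_pruned: dict[str, int]
    lead_pqtls: dict[str, str]
    shared_genes: list[str]
    independent_genes: list[str]
    mx_negative_genes: list[str]
    mr_negative_genes: list[str]
    discordant_genes: list[str]
    overlap: dict
    chains: pd.DataFrame
    sexdiff: pd.DataFrame
    coloc_table: pd.DataFrame
    twas_table: pd.DataFrame
    mr_ge_pe_table: pd.DataFrame
    mr_pe_outcome_table: pd.DataFrame
    stage_log: dict[str, int]

    def summary_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "n_samples": self.n_samples,
            "n_regions": self.n_regions,
            "n_variants": self.n_variants,
            "simes": {k: float(v) for k, v in self.simes.items()},
            "k": self.k,
            "alpha2": self.alpha2,
            "n_significant_variants": self.n_significant_variants,
            "n_pruned": self.n_pruned,
            "lead_pqtls": self.lead_pqtls,
            "shared_genes": self.shared_genes,
            "independent_genes": self.independent_genes,
            "mx_negative_genes": self.mx_negative_genes,
            "mr_negative_genes": self.mr_negative_genes,
            "discordant_genes": self.discordant_genes,
            "overlap": self.overlap,
            "stage_log": self.stage_log,
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
        self.chains.to_csv(out / "chains.tsv", sep="\t", index=False)
        self.sexdiff.to_csv(out / "sexdiff.tsv", sep="\t", index=False)
        self.coloc_table.to_csv(out / "coloc.tsv", sep="\t", index=False)
        self.twas_table.to_csv(out / "twas.tsv", sep="\t", index=False)
        self.mr_ge_pe_table.to_csv(out / "mr_ge_pe.tsv", sep="\t", index=False)
        self.mr_pe_outcome_table.to_csv(out / "mr_pe_outcome.tsv", sep="\t", index=False)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _gene_name(r: int) -> str:
    return f"gene{r:03d}"


def _stat_row(stats_df: pd.DataFrame, variant_id: str):
    rows = stats_df.loc[stats_df["variant_id"] == variant_id]
    return None if len(rows) == 0 else rows.iloc[0]


def run_all(config: PipelineConfig) -> RunReport:  # noqa: C901 - orchestration
    sim = config.sim
    stage = "simdata"
    try:
        geno = simulate_genotypes(sim)
        truth = make_truth(geno, sim)
        omics = simulate_omics(geno, truth, sim)
        y = simulate_outcome(omics.pe, omics.ge, truth, sim)
        n = sim.n_samples
        sizes = [int(round(f * n)) for f in config.split_fractions]
        sizes[-1] = min(sizes[-1], n - sum(sizes[:-1]))
        idx_ge, idx_pe1, idx_pe2, idx_out = make_split(n, sizes, seed=sim.seed)

        stage = "qtlscan"
        covar_full = omics.covariates
        sex = omics.sex
        genes = [_gene_name(r) for r in range(sim.n_regions)]
        region_cols = {r: geno.region_indices(r) for r in range(sim.n_regions)}

        def sub_geno(cols, samples) -> GenotypeMatrix:
            return GenotypeMatrix(
                geno.dosages[np.ix_(samples, cols)],
                geno.variants.iloc[cols].reset_index(drop=True),
            )

        pe_stats: dict[str, pd.DataFrame] = {}
        pe2_stats: dict[str, pd.DataFrame] = {}
        pe_sex_stats: dict[str, dict[str, pd.DataFrame]] = {}
        ge_stats: dict[str, dict[int, pd.DataFrame]] = {}
        for r, gene in enumerate(genes):
            cols = region_cols[r]
            g_pe1 = sub_geno(cols, idx_pe1)
            pe_stats[gene] = scan_region(
                g_pe1, omics.pe[r][idx_pe1], covariates=covar_full.iloc[idx_pe1]
            )
            g_pe2 = sub_geno(cols, idx_pe2)
            pe2_stats[gene] = scan_region(
                g_pe2, omics.pe[r][idx_pe2], covariates=covar_full.iloc[idx_pe2]
            )
            if config.sex_stratified:
                pe_sex_stats[gene] = {
                    stratum: scan_region(
                        g_pe1,
                        omics.pe[r][idx_pe1],
                        covariates=covar_full.iloc[idx_pe1][["age"]],
                        stratum=stratum,
                        sex=sex[idx_pe1],
                    )
                    for stratum in ("female", "male")
                }
            g_ge = sub_geno(cols, idx_ge)
            ge_stats[gene] = {
                t: scan_region(
                    g_ge,
                    omics.ge[r, t][idx_ge],
                    covariates=covar_full.iloc[idx_ge][["age"]],
                )
                for t in range(sim.n_tissues)
            }

        stage = "hfdr_ld"
        hres: HierFDRResult = hierarchical_fdr(pe_stats, alpha1=config.alpha1)
        lead_pqtls: dict[str, str] = {}
        n_pruned: dict[str, int] = {}
        for gene in hres.selected:
            stats_df = pe_stats[gene]
            sig = stats_df.iloc[hres.significant[gene]]
            if len(sig) == 0:
                continue
            lead_pqtls[gene] = str(lead_variant(sig)["variant_id"])
            r = genes.index(gene)
            pruned = priority_prune(sig, sub_geno(region_cols[r], np.arange(n)), config.r2_max)
            n_pruned[gene] = len(pruned)

        stage = "coloc"
        coloc_rows = []
        shared_genes, independent_genes = set(), set()
        for gene in hres.selected:
            for t in range(sim.n_tissues):
                res = colocalize(
                    ge_stats[gene][t], pe_stats[gene], threshold=config.pp_threshold
                )
                coloc_rows.append(
                    {
                        "gene_id": gene, "tissue": f"t{t}",
                        "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                        "pp3": res.pp3, "pp4": res.pp4,
                        "n_variants": res.n_variants, "verdict": res.verdict,
                    }
                )
                if res.verdict == "shared":
                    shared_genes.add(gene)
                elif res.verdict == "independent":
                    independent_genes.add(gene)
        coloc_table = pd.DataFrame(coloc_rows)

        stage = "twas"
        models: list[WeightModel] = []
        for rt in truth.regions:
            if rt.ge_causal is None:
                continue
            gene = genes[rt.region]
            vrow = geno.variants.iloc[rt.ge_causal]
            for t in range(sim.n_tissues):
                if rt.beta_ge[t] == 0:
                    continue
                models.append(
                    WeightModel(
                        gene_id=gene,
                        tissue=f"t{t}",
                        weights=pd.DataFrame(
                            {
                                "variant_id": [vrow["variant_id"]],
                                "effect_allele": [vrow["effect_allele"]],
                                "weight": [rt.beta_ge[t]],
                            }
                        ),
                    )
                )
        twas_results = [
            summary_twas(pe_stats[m.gene_id], m, geno) for m in models
        ]
        mx_negative = set()
        if twas_results:
            twas_table = results_frame(twas_results)
            sig_pairs, _ = hierarchical_fdr_tissues(twas_table, alpha1=config.alpha1)
            mx_negative = set(sig_pairs.loc[sig_pairs["z"] < 0, "gene_id"])
        else:
            twas_table = pd.DataFrame(
                columns=["gene_id", "tissue", "z", "effect", "p", "n_variants_used"]
            )

        stage = "mr_ge_pe"
        ge_pe_rows = []
        for gene in genes:
            for t in range(sim.n_tissues):
                inst = select_instrument(ge_stats[gene][t], config.instrument_p_max)
                if inst is None:
                    continue
                out_row = _stat_row(pe_stats[gene], inst["variant_id"])
                if out_row is None:
                    continue
                biv, siv, p = mr_ratio(
                    float(inst["beta"]), float(inst["se"]),
                    float(out_row["beta"]), float(out_row["se"]),
                )
                ge_pe_rows.append(
                    {
                        "gene_id": gene, "tissue": f"t{t}",
                        "variant_id": inst["variant_id"],
                        "beta_x": float(inst["beta"]), "se_x": float(inst["se"]),
                        "beta_y": float(out_row["beta"]), "se_y": float(out_row["se"]),
                        "beta_iv": biv, "se_iv": siv, "p": p,
                    }
                )
        mr_ge_pe = pd.DataFrame(ge_pe_rows)
        mr_negative = set()
        if len(mr_ge_pe):
            fam = {f"{row.gene_id}/{row.tissue}": row.gene_id for row in mr_ge_pe.itertuples()}
            hmr = hierarchical_fdr(
                {
                    g: grp["p"].to_numpy()
                    for g, grp in mr_ge_pe.groupby("gene_id", sort=True)
                },
                alpha1=config.alpha1,
            )
            mr_ge_pe["significant"] = False
            for g, grp in mr_ge_pe.groupby("gene_id", sort=True):
                sig_idx = hmr.significant.get(g, np.array([], dtype=int))
                mr_ge_pe.loc[grp.index[sig_idx], "significant"] = True
            mr_negative = set(
                mr_ge_pe.loc[mr_ge_pe["significant"] & (mr_ge_pe["beta_iv"] < 0), "gene_id"]
            )

        stage = "mr_pe_outcome"
        # disease associations (logistic) only at the instrument variants
        needed = set(lead_pqtls.values()) | set(mr_ge_pe["variant_id"]) if len(mr_ge_pe) else set(lead_pqtls.values())
        cad_stats = {}
        if needed:
            cols = sorted(geno.index_of(v) for v in needed)
            g_out = sub_geno(np.array(cols), idx_out)
            cad = scan_region(
                g_out, y[idx_out].astype(float),
                covariates=covar_full.iloc[idx_out], model="logistic",
            )
            cad_stats = {row["variant_id"]: row for _, row in cad.iterrows()}

        pe_cad_rows = []
        tested = []
        for gene, vid in lead_pqtls.items():
            lead = _stat_row(pe_stats[gene], vid)
            if lead is None or lead["p"] >= config.instrument_p_max or vid not in cad_stats:
                continue
            x_row = _stat_row(pe2_stats[gene], vid)  # independent PE estimate
            if x_row is None:
                continue
            yrow = cad_stats[vid]
            biv, siv, p = mr_ratio(
                float(x_row["beta"]), float(x_row["se"]),
                float(yrow["beta"]), float(yrow["se"]),
            )
            tested.append(gene)
            pe_cad_rows.append(
                {
                    "gene_id": gene, "variant_id": vid,
                    "beta_x": float(x_row["beta"]), "se_x": float(x_row["se"]),
                    "beta_y": float(yrow["beta"]), "se_y": float(yrow["se"]),
                    "beta_iv": biv, "se_iv": siv, "p": p,
                }
            )
        mr_pe_cad = pd.DataFrame(pe_cad_rows)
        if len(mr_pe_cad):
            mr_pe_cad["p_adjusted"] = np.minimum(mr_pe_cad["p"] * len(tested), 1.0)
            mr_pe_cad["significant"] = mr_pe_cad["p_adjusted"] <= config.alpha1

        stage = "mediation"
        chains: list[CausalChain] = []
        if len(mr_pe_cad) and len(mr_ge_pe):
            causal_proteins = set(mr_pe_cad.loc[mr_pe_cad["significant"], "gene_id"])
            for row in mr_ge_pe.itertuples():
                if row.gene_id not in causal_proteins or not row.significant:
                    continue
                leg1 = MRResult(
                    row.gene_id, "pe", row.variant_id,
                    row.beta_x, row.se_x, row.beta_y, row.se_y,
                    row.beta_iv, row.se_iv, row.p,
                )
                prow = mr_pe_cad.loc[mr_pe_cad["gene_id"] == row.gene_id].iloc[0]
                leg2 = MRResult(
                    row.gene_id, "outcome", prow["variant_id"],
                    prow["beta_x"], prow["se_x"], prow["beta_y"], prow["se_y"],
                    prow["beta_iv"], prow["se_iv"], prow["p"],
                )
                if row.variant_id not in cad_stats:
                    chains.append(mediation_chain(leg1, leg2, None, row.gene_id, row.tissue))
                    continue
                yrow = cad_stats[row.variant_id]
                tb, ts, tp = mr_ratio(row.beta_x, row.se_x, float(yrow["beta"]), float(yrow["se"]))
                leg_total = MRResult(
                    row.gene_id, "outcome", row.variant_id,
                    row.beta_x, row.se_x, float(yrow["beta"]), float(yrow["se"]),
                    tb, ts, tp,
                )
                chains.append(
                    mediation_chain(
                        leg1, leg2, leg_total, row.gene_id, row.tissue, alpha=config.chain_alpha
                    )
                )
        chains_table = chains_frame(chains) if chains else pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(CausalChain)]
        )

        stage = "concordance"
        discordant = set()
        for gene, vid in lead_pqtls.items():
            lead = _stat_row(pe_stats[gene], vid)
            betas, pvals = [], []
            for t in range(sim.n_tissues):
                row = _stat_row(ge_stats[gene][t], vid)
                if row is not None:
                    betas.append(float(row["beta"]))
                    pvals.append(float(row["p"]))
            if not betas:
                continue
            sig = np.asarray(pvals) <= config.eqtl_alpha
            if not (sig & (np.asarray(betas) != 0)).any():
                continue
            summary = direction_classify(
                float(lead["beta"]), betas, significant=np.asarray(pvals),
                gene_id=gene, threshold=config.discordance_threshold,
            )
            if summary.verdict == "predominantly_discordant":
                discordant.add(gene)

        overlap = overlap_sets(mx_negative, mr_negative, discordant)

        stage = "sexdiff"
        sd_rows = []
        if config.sex_stratified:
            for gene, vid in lead_pqtls.items():
                frow = _stat_row(pe_sex_stats[gene]["female"], vid)
                mrow = _stat_row(pe_sex_stats[gene]["male"], vid)
                if frow is None or mrow is None:
                    continue
                t_stat, p = sex_difference_test(
                    float(frow["beta"]), float(frow["se"]),
                    float(mrow["beta"]), float(mrow["se"]),
                )
                sd_rows.append(
                    {
                        "gene_id": gene, "variant_id": vid,
                        "beta_female": float(frow["beta"]), "se_female": float(frow["se"]),
                        "beta_male": float(mrow["beta"]), "se_male": float(mrow["se"]),
                        "t": t_stat, "p": p,
                    }
                )
        sexdiff = pd.DataFrame(sd_rows)
    except Exception as exc:  # annotate failures with the stage name
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunReport(
        config_hash=config.config_hash(),
        seed=sim.seed,
        version=__version__,
        n_samples=sim.n_samples,
        n_regions=sim.n_regions,
        n_variants=geno.n_variants,
        simes=hres.simes,
        k=hres.k,
        alpha2=hres.alpha2,
        n_significant_variants=hres.n_significant(),
        n_pruned=n_pruned,
        lead_pqtls=lead_pqtls,
        shared_genes=sorted(shared_genes),
        independent_genes=sorted(independent_genes),
        mx_negative_genes=sorted(mx_negative),
        mr_negative_genes=sorted(mr_negative),
        discordant_genes=sorted(discordant),
        overlap=overlap,
        chains=chains_table,
        sexdiff=sexdiff,
        coloc_table=coloc_table,
        twas_table=twas_table,
        mr_ge_pe_table=mr_ge_pe,
        mr_pe_outcome_table=mr_pe_cad,
        stage_log={
            "regions_scanned": sim.n_regions,
            "regions_selected": hres.k,
            "coloc_pairs": len(coloc_table),
            "twas_pairs": len(twas_table),
            "mr_ge_pe_tests": len(mr_ge_pe),
            "mr_pe_outcome_tests": len(mr_pe_cad),
            "chains": len(chains_table),
        },
    )


def demo_config(
    n_causal: int = 5, n_null: int = 60, seed: int = 7, n_tissues: int = 3
) -> PipelineConfig:
    """Demo study: a few discordant shared-architecture genes among nulls.

    The causal genes carry a shared GE/PE causal variant with opposite
    effect signs (discordant) and their protein levels raise disease
    risk; everything else is null.  The end-to-end run should place
    exactly the causal genes in the central overlap cell.
    """
    n_regions = n_causal + n_null
    archs = ["shared"] * n_causal + ["null"] * n_null
    signs = ["discordant"] * n_causal + ["concordant"] * n_null
    sim = SimConfig(
        n_samples=4500,
        n_variants_per_region=24,
        n_regions=n_regions,
        n_tissues=n_tissues,
        maf_range=(0.1, 0.5),
        ld_decay=0.8,
        architectures=tuple(archs),
        sign_patterns=tuple(signs),
        ge_h2=0.15,
        pe_h2=0.15,
        pathway_coupling=0.0,
        theta_pe=0.8,
        mediation_fraction=1.0,
        prevalence=0.3,
        seed=seed,
    )
    return PipelineConfig(
        sim=sim, split_fractions=(0.22, 0.22, 0.22, 0.34)
    )
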