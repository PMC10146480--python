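"""Factorial heritability analysis: SNP sets x prevalences x covariate models.

Reproduces, on simulated or PLINK-format cohorts, the full analysis grid of a
late-onset-disease heritability study: SNP sets {all SNPs, all minus the APOE
region, all minus APOE and GWAS-hit flanks, gene-set only} crossed with
liability thresholds at 2%, 5% and 15% prevalence and with two covariate
models (PCs + sex, and PCs + sex + age). Each SNP set is analysed with
GREML-LDMS (LD-score quartiles within MAF groups, one GRM per stratum,
strata recomputed within each SNP set) except the gene-set, which is fitted
as a single GRM; observed-scale estimates are converted to the liability
scale at each prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import plink_io
from .liability import AgeOnsetModel, observed_to_liability
from .regions import RegionSet, apoe_region_set
from .relatedness import compute_grm, exclude_regions, make_ldms_strata, segment_ld_scores
from .reml import design_matrix, pcs_from_grm, reml_fit
from .simulate import (
    ArchitectureSpec,
    GenotypeMatrix,
    ascertain,
    draw_effects,
    simulate_genotypes,
    simulate_liability_onset,
)

__all__ = [
    "SimulationSpec",
    "ExperimentConfig",
    "run_experiment",
    "geneset_proportion",
    "summarize_deltas",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)

SNP_SETS = ("all", "no_apoe", "no_apoe_gwas", "geneset")


@dataclass
class SimulationSpec:
    """Study-design knobs for one simulated cohort replicate."""

    n_cases: int = 500
    n_controls: int = 500
    n_population: int = 8000
    m_snps: int = 1500
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    ld_block_size: int = 20
    ld_rho: float = 0.5
    case_age_dist: tuple = (75.0, 90.0)
    control_age_dist: tuple = (75.0, 90.0)
    screened: bool = True
    misdiagnosis_rate: float = 0.0
    n_gwas_hits: int = 3
    anchor_points: tuple = ((65.0, 0.02), (75.0, 0.05), (85.0, 0.15))


@dataclass
class ExperimentConfig:
    """Inputs and factorial settings for :func:`run_experiment`.

    Exactly one of ``plink_prefix`` (with phenotype/covariate files) or
    ``simulation`` must be set.
    """

    plink_prefix: str | None = None
    pheno_path: str | None = None
    covar_path: str | None = None
    apoe_bed: str | None = None
    gwas_bed: str | None = None
    geneset_path: str | None = None
    simulation: SimulationSpec | None = None
    prevalences: tuple[float, ...] = (0.02, 0.05, 0.15)
    covariate_models: tuple[str, ...] = ("pcs_sex", "pcs_sex_age")
    snp_sets: tuple[str, ...] = SNP_SETS
    n_pcs: int = 5
    gwas_flank_bp: int = 500_000
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for K in self.prevalences:
            if not (0.0 < K < 1.0):
                raise ValueError(f"prevalence {K!r} outside (0, 1)")
        has_real = self.plink_prefix is not None
        has_sim = self.simulation is not None
        if has_real == has_sim:
            raise ValueError("exactly one of plink_prefix or simulation must be set")
        unknown = set(self.snp_sets) - set(SNP_SETS)
        if unknown:
            raise ValueError(f"unknown snp_sets {sorted(unknown)}; choose from {SNP_SETS}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            arch = sim.pop("arch", None)
            spec = SimulationSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()})
            if arch is not None:
                spec.arch = ArchitectureSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in arch.items()})
            raw["simulation"] = spec
        for key in ("prevalences", "covariate_models", "snp_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CohortData:
    """Everything one factorial run needs: genotypes, phenotypes, regions."""

    genotypes: GenotypeMatrix
    status: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    apoe: RegionSet
    gwas_hits: RegionSet
    geneset_ids: list[str]
    truth: dict = field(default_factory=dict)


def simulate_cohort(spec: SimulationSpec, seed: int) -> CohortData:
    """One simulated, ascertained cohort under the given study design.

    GWAS-hit analogs are the ``n_gwas_hits`` largest per-SNP variance
    contributors outside the APOE-analog window, as zero-width intervals
    to be expanded by the pipeline's 0.5 Mb flank.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    G = simulate_genotypes(
        spec.n_population,
        spec.m_snps,
        maf_range=spec.arch.maf_range,
        ld_block_size=spec.ld_block_size,
        ld_rho=spec.ld_rho,
        seed=int(seeds[0]),
    )
    effects = draw_effects(G.snp_meta, spec.arch, seed=int(seeds[1]))
    onset_model = AgeOnsetModel(spec.anchor_points)
    pop = simulate_liability_onset(G, effects, onset_model, seed=int(seeds[2]))
    asc = ascertain(
        pop,
        spec.n_cases,
        spec.n_controls,
        case_age_dist=spec.case_age_dist,
        control_age_dist=spec.control_age_dist,
        screened=spec.screened,
        misdiagnosis_rate=spec.misdiagnosis_rate,
        seed=int(seeds[3]),
    )
    cohort = asc.cohort
    Gs = G.take_samples(cohort["pop_index"].to_numpy())

    apoe = apoe_region_set()
    meta = G.snp_meta
    contrib = effects.beta_std**2
    outside = ~apoe.contains(meta["chrom"].to_numpy(), meta["pos_bp"].to_numpy())
    cand = np.flatnonzero(outside & (contrib > 0))
    top = cand[np.argsort(contrib[cand])[::-1][: spec.n_gwas_hits]]
    hits = RegionSet(
        [(int(meta["chrom"].iloc[i]), int(meta["pos_bp"].iloc[i]), int(meta["pos_bp"].iloc[i])) for i in top],
        label="gwas_hits",
    )
    truth = {
        "h2_liability": spec.arch.h2_liability_total,
        "major_locus_share": spec.arch.major_locus_share,
        "geneset_h2_share": spec.arch.geneset_h2_share,
        "apoe_window_variance": effects.variance_in(
            apoe.contains(meta["chrom"].to_numpy(), meta["pos_bp"].to_numpy())
        ),
        "latent_control_fraction": asc.latent_control_fraction,
        "n_misdiagnosed": asc.n_misdiagnosed,
    }
    return CohortData(
        genotypes=Gs,
        status=cohort["status"].to_numpy(),
        sex=cohort["sex"].to_numpy(),
        age=cohort["age_years"].to_numpy(),
        apoe=apoe,
        gwas_hits=hits,
        geneset_ids=effects.geneset_ids,
        truth=truth,
    )


def _load_real_cohort(config: ExperimentConfig) -> CohortData:
    G = plink_io.read_plink(config.plink_prefix)
    pheno = plink_io.read_pheno(config.pheno_path)
    covar = plink_io.read_covar(config.covar_path)
    df = pd.DataFrame({"iid": G.sample_ids}).merge(pheno, on="iid").merge(covar, on="iid")
    if len(df) != len(G.sample_ids):
        raise ValueError("phenotype/covariate files do not cover every genotyped sample")
    apoe = RegionSet.from_bed(config.apoe_bed, label="APOE") if config.apoe_bed else apoe_region_set()
    hits = RegionSet.from_bed(config.gwas_bed, label="gwas_hits") if config.gwas_bed else RegionSet([], "gwas_hits")
    geneset: list[str] = []
    if config.geneset_path:
        path = Path(config.geneset_path)
        if path.suffix == ".bed":
            gs_regions = RegionSet.from_bed(path, label="geneset")
            mask = gs_regions.contains(G.snp_meta["chrom"].to_numpy(), G.snp_meta["pos_bp"].to_numpy())
            geneset = G.snp_meta.loc[mask, "snp_id"].tolist()
        else:
            geneset = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return CohortData(
        genotypes=G,
        status=df["status"].to_numpy(),
        sex=df["sex"].to_numpy(),
        age=df["age"].to_numpy(),
        apoe=apoe,
        gwas_hits=hits,
        geneset_ids=geneset,
    )


def _snp_set_ids(name: str, data: CohortData, config: ExperimentConfig) -> list[str]:
    meta = data.genotypes.snp_meta
    if name == "all":
        return meta["snp_id"].tolist()
    if name == "no_apoe":
        return exclude_regions(meta, data.apoe)
    if name == "no_apoe_gwas":
        kept = set(exclude_regions(meta, data.apoe))
        kept &= set(exclude_regions(meta, data.gwas_hits, flank_bp=config.gwas_flank_bp))
        return [s for s in meta["snp_id"] if s in kept]
    if name == "geneset":
        return list(data.geneset_ids)
    raise ValueError(f"unknown SNP set {name!r}")


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full factorial analysis and return the tidy results table.

    One row per (snp_set, covariate_model, prevalence) cell with columns
    h2_obs, se_h2_obs, h2_liab, p_lrt, n_snps, n_strata, n_cases,
    n_controls, converged. Non-converged cells are flagged, not fatal.
    """
    data = simulate_cohort(config.simulation, config.seed) if config.simulation else _load_real_cohort(config)
    G = data.genotypes
    y = data.status.astype(float)
    n_cases = int(data.status.sum())
    n_controls = int(len(y) - n_cases)

    grm_all = compute_grm(G)
    pcs = pcs_from_grm(grm_all, config.n_pcs)
    designs = {}
    for model in config.covariate_models:
        if model == "pcs_sex":
            designs[model] = design_matrix(len(y), pcs, data.sex)
        elif model == "pcs_sex_age":
            designs[model] = design_matrix(len(y), pcs, data.sex, data.age)
        else:
            raise ValueError(f"unknown covariate model {model!r}")

    rows = []
    for snp_set in config.snp_sets:
        ids = _snp_set_ids(snp_set, data, config)
        if not ids:
            logger.warning("SNP set %s is empty; skipping", snp_set)
            continue
        Gs = G.subset_snps(ids)
        if snp_set == "geneset":
            grms = [compute_grm(Gs)]
            n_strata = 1
        else:
            ld = segment_ld_scores(Gs)
            mafs = np.minimum(Gs.snp_meta["allele_freq"], 1 - Gs.snp_meta["allele_freq"]).to_numpy()
            strata = make_ldms_strata(ld, mafs, snp_ids=Gs.snp_meta["snp_id"].tolist())
            grms = [compute_grm(Gs, snp_subset=strata.snp_ids(s)) for s in sorted(strata.definitions)]
            n_strata = len(grms)
        n_snps = sum(g.n_snps for g in grms)
        for model, X in designs.items():
            fit = reml_fit(y, X, grms)
            if not fit.converged:
                logger.warning("cell (%s, %s) did not converge", snp_set, model)
            for K in config.prevalences:
                rows.append(
                    {
                        "snp_set": snp_set,
                        "covariate_model": model,
                        "prevalence": K,
                        "h2_obs": fit.h2_observed,
                        "se_h2_obs": fit.se_h2,
                        "h2_liab": observed_to_liability(fit.h2_observed, K, float(np.mean(y))),
                        "p_lrt": fit.p_lrt,
                        "n_snps": n_snps,
                        "n_strata": n_strata,
                        "n_cases": n_cases,
                        "n_controls": n_controls,
                        "converged": fit.converged,
                    }
                )
    results = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        if data.truth:
            plink_io.write_truth_json(out / "truth.json", data.truth)
    return results


def geneset_proportion(results: pd.DataFrame) -> pd.DataFrame:
    """Gene-set share of heritability per prevalence (and its SNP fraction).

    ``proportion_h2 = h2(gene-set fit) / h2(all-SNP fit)`` within each
    (prevalence, covariate model) cell; because the liability transform is a
    multiplicative factor shared by numerator and denominator, the proportion
    is identical across prevalences — which is why published per-prevalence
    ranges of this quantity are narrow.
    """
    need = {"geneset", "all"}
    have = set(results["snp_set"])
    if not need <= have:
        raise ValueError(f"results must contain snp_sets {sorted(need)}; have {sorted(have)}")
    rows = []
    for (model, K), grp in results.groupby(["covariate_model", "prevalence"]):
        allrow = grp[grp["snp_set"] == "all"].iloc[0]
        gsrow = grp[grp["snp_set"] == "geneset"].iloc[0]
        prop = gsrow["h2_liab"] / allrow["h2_liab"] if allrow["h2_liab"] > 0 else np.nan
        rows.append(
            {
                "covariate_model": model,
                "prevalence": K,
                "proportion_h2": prop,
                "proportion_snps": gsrow["n_snps"] / allrow["n_snps"],
            }
        )
    return pd.DataFrame(rows)


def summarize_deltas(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean and SD of the h2 drop from region exclusions, over replicates.

    For each (prevalence, covariate model) cell: ``delta_apoe`` is
    h2(all) - h2(no_apoe) and ``delta_gwas`` the further drop
    h2(no_apoe) - h2(no_apoe_gwas), paired within replicate, reported on the
    liability scale.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates to summarize deltas")
    recs = []
    for i, res in enumerate(replicates):
        for (model, K), grp in res.groupby(["covariate_model", "prevalence"]):
            by = grp.set_index("snp_set")["h2_liab"]
            if {"all", "no_apoe"} <= set(by.index):
                recs.append(
                    {
                        "replicate": i,
                        "covariate_model": model,
                        "prevalence": K,
                        "delta_apoe": by["all"] - by["no_apoe"],
                        "delta_gwas": by["no_apoe"] - by["no_apoe_gwas"]
                        if "no_apoe_gwas" in by.index
                        else np.nan,
                    }
                )
    df = pd.DataFrame(recs)
    out = (
        df.groupby(["covariate_model", "prevalence"])
        .agg(
            mean_delta_apoe=("delta_apoe", "mean"),
            sd_delta_apoe=("delta_apoe", "std"),
            mean_delta_gwas=("delta_gwas", "mean"),
            sd_delta_gwas=("delta_gwas", "std"),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
    return out
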