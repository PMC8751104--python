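"""End-to-end orchestration of the covariate-search pipeline.

Chains the stages: phenotype cleaning -> per-environment GBLUP (step 0)
-> stage-window covariates and similarity kernels (steps 1-2) -> pairwise
bivariate REML genetic correlations (step 3) -> covariate scan with
cluster pruning (step 4) -> slopes, GWAS, FDR, regions and subsampling
(step 5). Every stochastic stage draws from a named substream of the run
seed, so a run is reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import env_covariates, mixed_models, scan, slopes_gwas
from .io_config import GenotypeMatrix, RunConfig, stage_rng

logger = logging.getLogger("ecgc")


def fixed_design(records: pd.DataFrame) -> np.ndarray:
    """Intercept + year dummies (+ management dummies when present)."""
    n = len(records)
    cols = [np.ones(n)]
    for col in ("year", "management"):
        if col in records.columns and records[col].nunique() > 1:
            d = pd.get_dummies(records[col].astype(str), drop_first=True)
            cols.append(d.to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_environments(trials: pd.DataFrame, trait: str, grm: pd.DataFrame,
                     config: RunConfig) -> dict[str, mixed_models.GBLUPFit]:
    """Step 0: single-trait GBLUP per environment; returns env -> fit."""
    fits: dict[str, mixed_models.GBLUPFit] = {}
    usable = trials[trials[trait].notna() & trials["variety_id"].isin(grm.index)]
    for env, recs in usable.groupby("environment_id", sort=True):
        if recs["variety_id"].nunique() < 2:
            logger.warning("environment %r: <2 varieties with %s records; skipped", env, trait)
            continue
        X = fixed_design(recs)
        fit = mixed_models.fit_gblup(
            recs[trait].to_numpy(dtype=float), X, list(recs["variety_id"]), grm,
            tol=config.reml_tol, max_iter=config.reml_max_iter,
            environment_id=str(env), trait=trait)
        fit.records = recs.assign(y_adj=fit.y_adj)[["variety_id", "year", "y_adj"]]
        fits[str(env)] = fit
    return fits


def genetic_correlation_matrix(fits: dict[str, mixed_models.GBLUPFit],
                               grm: pd.DataFrame, config: RunConfig,
                               trait: str = "") -> pd.DataFrame:
    """Step 3: pairwise bivariate REML -> assembled genetic correlation."""
    envs = sorted(fits)
    rng = stage_rng(config.rng_seed, f"match_records:{trait}")
    pairwise = {}
    for (ej, ek) in mixed_models.environment_pairs(envs):
        fj, fk = fits[ej], fits[ek]
        paired = mixed_models.match_records(
            fj.records.rename(columns={"y_adj": "value"}),
            fk.records.rename(columns={"y_adj": "value"}), rng)
        init = (fj.sigma_u2, fj.sigma_e2, fk.sigma_u2, fk.sigma_e2)
        try:
            pc = mixed_models.fit_bivariate(paired, grm, tol=config.reml_tol,
                                            max_iter=config.reml_max_iter,
                                            env_j=ej, env_k=ek, init=init)
        except ValueError as exc:
            logger.warning("pair (%s, %s) skipped: %s", ej, ek, exc)
            pc = mixed_models.PairwiseCovariance(ej, ek, np.eye(2), np.eye(2),
                                                 converged=False)
        if not pc.converged:
            logger.warning("pair (%s, %s) flagged non-converged", ej, ek)
        pairwise[(ej, ek)] = pc
    return mixed_models.assemble_correlation(pairwise, envs)


@dataclass
class PipelineResult:
    cov_table: pd.DataFrame
    gen_corr: dict[str, pd.DataFrame]
    scan: scan.ScanResult
    fits: dict[str, dict[str, mixed_models.GBLUPFit]]  # trait -> env -> fit
    slopes: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    gwas: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    fdr_p: dict[tuple[str, str], float | None] = field(default_factory=dict)
    regions: dict[tuple[str, str], list] = field(default_factory=dict)

    @property
    def selected(self) -> pd.DataFrame:
        return self.scan.table[self.scan.table["selected"]]


def run_all(gm: GenotypeMatrix, trials: pd.DataFrame, weather: pd.DataFrame,
            traits: list[str], config: RunConfig, grm: pd.DataFrame | None = None,
            with_gwas: bool = True, with_subsampling: bool = True) -> PipelineResult:
    """Run the full pipeline on one dataset."""
    from .grm import filter_maf, mean_impute, vanraden_grm

    gm_imputed = mean_impute(gm)
    if grm is None:
        grm = vanraden_grm(gm_imputed)
    gm_qc = filter_maf(gm_imputed, config.maf_min)

    for trait in traits:
        trials = env_covariates.mask_outliers(trials, trait)

    cov_table = env_covariates.build_covariate_table(trials, weather, config)

    fits_all: dict[str, dict[str, mixed_models.GBLUPFit]] = {}
    gen_corr: dict[str, pd.DataFrame] = {}
    for trait in traits:
        fits = fit_environments(trials, trait, grm, config)
        fits_all[trait] = fits
        gen_corr[trait] = genetic_correlation_matrix(fits, grm, config, trait)

    labels = scan.cluster_covariates(cov_table,
                                     rng=stage_rng(config.rng_seed, "gap_statistic"))
    scan_res = scan.scan_covariates(cov_table, gen_corr, alpha=config.scan_alpha,
                                    cluster_labels=labels)
    result = PipelineResult(cov_table=cov_table, gen_corr=gen_corr,
                            scan=scan_res, fits=fits_all)

    for row in result.selected.itertuples(index=False):
        key = (row.trait, row.covariate_id)
        slopes = slopes_gwas.estimate_slopes(fits_all[row.trait], cov_table,
                                             row.covariate_id)
        result.slopes[key] = slopes
        if not with_gwas:
            continue
        gwas = slopes_gwas.mm_gwas(slopes["slope"], gm_qc, grm,
                                   maf_min=config.maf_min, tol=config.reml_tol,
                                   max_iter=config.reml_max_iter)
        result.gwas[key] = gwas
        thr = slopes_gwas.fdr_threshold(gwas["p"].to_numpy(), config.fdr_level)
        result.fdr_p[key] = thr
        if thr is None:
            result.regions[key] = []
            continue
        sig = gwas[gwas["p"] <= thr]
        regions = slopes_gwas.group_regions(sig, config.region_gap_bp)
        if with_subsampling and regions:
            rng = stage_rng(config.rng_seed, f"subsample:{row.trait}:{row.covariate_id}")
            regions = slopes_gwas.subsample_validate(
                slopes["slope"], gm_qc, grm, regions, thr, config, rng)
        result.regions[key] = regions
    return result
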