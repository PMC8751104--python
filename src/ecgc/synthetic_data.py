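"""Synthetic multi-environment trial data with planted G x E structure.

Generates genotypes, daily weather and phenotype records that obey the
reaction-norm model the pipeline assumes: additive effects at environment
j decompose as u_j = sigma_uj (beta x_j + u~_j), with per-variety slopes
beta ~ a few QTLs plus a kinship-distributed polygenic term (total
variance sigma_beta^2), a planted covariate x_j injected into one weather
factor over one stage window, and residual genetic effects u~ with
exchangeable between-environment correlation. Every pipeline stage is
therefore testable end to end without any real (restricted) SNP panel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .env_covariates import assign_stages, covariate_id
from .grm import vanraden_grm
from .io_config import GenotypeMatrix, RunConfig, stage_rng

logger = logging.getLogger("ecgc")


@dataclass
class SynthConfig:
    """Generator settings; defaults are the package's reference conditions.

    The reference scale uses one weather factor and 6 growth stages
    (21 covariates), which exercises the full covariate machinery quickly;
    ``full_scale`` switches to the 14-factor, 30-stage layout (6,510
    covariates).
    """

    n_varieties: int = 300
    n_snps: int = 2000
    n_chrom: int = 5
    n_env: int = 20
    years_per_env: int = 3
    n_qtl: int = 3
    sigma_beta2: float = 1.0
    h2: float = 0.5
    residual_rho: float = 0.3
    qtl_fraction: float = 0.5  # share of slope variance carried by the QTLs
    n_pre_stages: int = 2
    n_post_stages: int = 4
    planted_factor: str = "tmean"
    planted_window: tuple[int, int] = (2, 4)  # 1-based inclusive stage span
    full_scale: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.full_scale:
            self.n_pre_stages, self.n_post_stages = 10, 20
        if min(self.n_varieties, self.n_snps, self.n_chrom, self.n_env,
               self.years_per_env) < 1 or self.n_qtl < 0:
            raise ValueError("all counts must be >= 1 (n_qtl >= 0)")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if self.sigma_beta2 < 0:
            raise ValueError("sigma_beta2 must be >= 0")
        S = self.n_pre_stages + self.n_post_stages
        a, b = self.planted_window
        if not 1 <= a <= b <= S:
            raise ValueError("planted_window outside stage range")

    @property
    def factors(self) -> list[str]:
        if self.full_scale:
            return [self.planted_factor] + [f"noise{i:02d}" for i in range(1, 14)]
        return [self.planted_factor]

    @property
    def causal_covariate(self) -> str:
        return covariate_id(self.planted_factor, *self.planted_window)

    def run_config(self) -> RunConfig:
        return RunConfig(n_pre_stages=self.n_pre_stages,
                         n_post_stages=self.n_post_stages,
                         rng_seed=self.rng_seed)


@dataclass
class SynthTruth:
    """Ground truth of one generated dataset."""

    x: pd.Series                  # planted covariate per environment
    beta: pd.Series               # true slope per variety
    qtl_snps: list[str]
    causal_covariate: str
    sigma_beta2: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "x": self.x.to_dict(),
                "beta": self.beta.to_dict(),
                "qtl_snps": self.qtl_snps,
                "causal_covariate": self.causal_covariate,
                "sigma_beta2": self.sigma_beta2,
            }, fh, indent=1)


def _simulate_genotypes(cfg: SynthConfig, rng: np.random.Generator) -> GenotypeMatrix:
    p = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    doses = rng.binomial(2, p, size=(cfg.n_varieties, cfg.n_snps)).astype(float)
    ids = [f"V{i:04d}" for i in range(cfg.n_varieties)]
    snps = [f"S{j:05d}" for j in range(cfg.n_snps)]
    per_chrom = int(np.ceil(cfg.n_snps / cfg.n_chrom))
    chrom = [f"chr{j // per_chrom + 1}" for j in range(cfg.n_snps)]
    bp = [200_000 * (j % per_chrom + 1) for j in range(cfg.n_snps)]
    gm = GenotypeMatrix(pd.DataFrame(doses, index=ids, columns=snps),
                        pd.DataFrame({"chrom": chrom, "bp": bp}, index=snps))
    return gm


def _simulate_beta(cfg: SynthConfig, gm: GenotypeMatrix, L_g: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    q = cfg.n_varieties
    if cfg.sigma_beta2 == 0:
        return np.zeros(q), []
    maf = gm.maf.to_numpy()
    eligible = np.nonzero(maf > 0.2)[0]
    qtl_idx = rng.choice(eligible, size=min(cfg.n_qtl, len(eligible)), replace=False)
    beta = np.zeros(q)
    qtl_ids = []
    if len(qtl_idx):
        var_each = cfg.qtl_fraction * cfg.sigma_beta2 / len(qtl_idx)
        for j in qtl_idx:
            dose = gm.doses.iloc[:, j].to_numpy()
            p = dose.mean() / 2
            eff = np.sqrt(var_each / max(2 * p * (1 - p), 1e-8)) * rng.choice([-1.0, 1.0])
            beta += eff * (dose - 2 * p)
            qtl_ids.append(gm.doses.columns[j])
    poly_var = (1 - cfg.qtl_fraction) * cfg.sigma_beta2
    beta += np.sqrt(poly_var) * (L_g @ rng.normal(size=q))
    return beta, qtl_ids


def generate_dataset(cfg: SynthConfig) -> tuple[GenotypeMatrix, pd.DataFrame,
                                                pd.DataFrame, SynthTruth]:
    """Generate (genotypes, trials, weather, truth) under the planted model."""
    rng_geno = stage_rng(cfg.rng_seed, "synth_genotypes")
    rng_beta = stage_rng(cfg.rng_seed, "synth_beta")
    rng_x = stage_rng(cfg.rng_seed, "synth_x")
    rng_wth = stage_rng(cfg.rng_seed, "synth_weather")
    rng_phe = stage_rng(cfg.rng_seed, "synth_phenotypes")

    gm = _simulate_genotypes(cfg, rng_geno)
    G = vanraden_grm(gm)
    q = cfg.n_varieties
    Gm = G.to_numpy() + 1e-6 * np.eye(q)
    L_g = np.linalg.cholesky(Gm)
    # scale so each variety's polygenic variance is ~1 on average
    L_g = L_g / np.sqrt(np.mean(np.diag(Gm)))

    beta, qtl_ids = _simulate_beta(cfg, gm, L_g, rng_beta)

    envs = [f"E{j:02d}" for j in range(cfg.n_env)]
    x = rng_x.uniform(-0.8, 0.8, size=cfg.n_env)
    if np.any(x**2 * cfg.sigma_beta2 > 1):
        raise ValueError("covariate effect too large for unit genetic variance")

    # residual genetic effects: exchangeable correlation across environments
    resid_var = np.clip(1.0 - x**2 * cfg.sigma_beta2, 0.05, None)
    R = (1 - cfg.residual_rho) * np.eye(cfg.n_env) + cfg.residual_rho
    Sig = np.sqrt(resid_var)[:, None] * R * np.sqrt(resid_var)[None, :]
    L_e = np.linalg.cholesky(Sig + 1e-10 * np.eye(cfg.n_env))
    u_resid = L_g @ rng_phe.normal(size=(q, cfg.n_env)) @ L_e.T
    U = beta[:, None] * x[None, :] + u_resid  # sigma_uj = 1

    years = [2001 + t for t in range(cfg.years_per_env)]
    year_eff = {yr: rng_phe.normal(0, 0.5) for yr in years}
    sigma_e2 = (1 - cfg.h2) / cfg.h2  # var(u) ~ 1 per environment

    # shared phenology within an environment-year
    phenology = {}
    for j, env in enumerate(envs):
        for yr in years:
            sow = pd.Timestamp(yr, 5, 10) + pd.Timedelta(days=int(rng_wth.integers(-5, 6)))
            flw = sow + pd.Timedelta(days=int(50 + rng_wth.integers(-5, 6)))
            mat = flw + pd.Timedelta(days=int(60 + rng_wth.integers(-8, 9)))
            phenology[(env, yr)] = (sow, flw, mat)

    weather = _simulate_weather(cfg, envs, years, phenology, x, rng_wth)

    ids = list(gm.doses.index)
    rows = []
    e_noise = rng_phe.normal(0, np.sqrt(sigma_e2), size=(q, cfg.n_env, len(years)))
    for j, env in enumerate(envs):
        for t, yr in enumerate(years):
            sow, flw, mat = phenology[(env, yr)]
            for v in range(q):
                rows.append((ids[v], env, yr, sow.date().isoformat(),
                             flw.date().isoformat(), mat.date().isoformat(),
                             5.0 + year_eff[yr] + U[v, j] + e_noise[v, j, t]))
    trials = pd.DataFrame(rows, columns=["variety_id", "environment_id", "year",
                                         "sowing_date", "flowering_date",
                                         "maturity_date", "yield"])
    for c in ("sowing_date", "flowering_date", "maturity_date"):
        trials[c] = pd.to_datetime(trials[c])

    truth = SynthTruth(x=pd.Series(x, index=envs), beta=pd.Series(beta, index=ids),
                       qtl_snps=qtl_ids, causal_covariate=cfg.causal_covariate,
                       sigma_beta2=cfg.sigma_beta2)
    return gm, trials, weather, truth


def _simulate_weather(cfg: SynthConfig, envs, years, phenology, x,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Daily weather; the planted factor's stage-window mean is 20 + 5 x_j."""
    a, b = cfg.planted_window
    frames = []
    for j, env in enumerate(envs):
        target = 20.0 + 5.0 * x[j]
        for yr in years:
            sow, flw, mat = phenology[(env, yr)]
            part = assign_stages(sow, flw, mat, cfg.n_pre_stages, cfg.n_post_stages)
            dates = pd.date_range(sow - pd.Timedelta(days=2), mat + pd.Timedelta(days=2),
                                  freq="D")
            for fac in cfg.factors:
                if fac == cfg.planted_factor:
                    vals = pd.Series(20.0 + rng.normal(0, 2.0, size=len(dates)),
                                     index=dates)
                    # centre the noise within each planted-window stage so the
                    # stage means (hence the span covariate) hit the target
                    for s in range(a - 1, b):
                        days = part.stages[s]
                        vals.loc[days] = target + (vals.loc[days] - vals.loc[days].mean())
                else:
                    vals = pd.Series(10.0 + rng.normal(0, 2.0, size=len(dates)),
                                     index=dates)
                frames.append(pd.DataFrame({"environment_id": env, "date": dates,
                                            "factor": fac, "value": vals.to_numpy()}))
    return pd.concat(frames, ignore_index=True)


def write_dataset(gm: GenotypeMatrix, trials: pd.DataFrame, weather: pd.DataFrame,
                  truth: SynthTruth, outdir: str | Path) -> None:
    """Write the generated dataset in the CSV formats the readers consume."""
    from .io_config import write_genotypes, write_trials, write_weather

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(gm, outdir / "genotypes.csv", outdir / "snp_map.csv")
    write_trials(trials, outdir / "trials.csv")
    write_weather(weather, outdir / "weather.csv")
    truth.to_json(outdir / "truth.json")
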