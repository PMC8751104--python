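"""Self-validation studies: combinatorics identities and parameter recovery.

These routines exercise the estimation machinery against data generated
under the model's own assumptions. They back the acceptance test suite and
the standalone acceptance script, and are useful as a health check after
any numerical change.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .env_covariates import span_covariates
from .grm import vanraden_grm
from .io_config import stage_rng
from .mixed_models import environment_pairs, fit_bivariate, fit_gblup
from .scan import bonferroni_threshold
from .slopes_gwas import estimate_slopes
from .synthetic_data import SynthConfig, _simulate_genotypes, generate_dataset

logger = logging.getLogger("ecgc")


def combinatorics(n_pre_stages: int = 10, n_post_stages: int = 20,
                  n_factors: int = 14, n_traits: int = 6,
                  n_environments: int = 52, alpha: float = 0.05) -> dict:
    """Counting identities of the covariate search, computed, not assumed.

    The span covariates are enumerated explicitly and the environment pairs
    are materialised, so these values are genuine outputs of the code paths
    the pipeline uses.
    """
    S = n_pre_stages + n_post_stages
    spans = span_covariates(np.zeros(S))
    per_factor = len(spans)
    total = per_factor * n_factors
    return {
        "stages": S,
        "covariates_per_factor": per_factor,
        "covariates_total": total,
        "bonferroni_threshold": bonferroni_threshold(total, n_traits, alpha),
        "n_environment_pairs": len(environment_pairs(range(n_environments))),
    }


def matched_fill_bound(n_records: int, n_varieties: int, n_environments: int) -> float:
    """Upper bound on the fill of the varieties x environments record grid."""
    if min(n_records, n_varieties, n_environments) < 1:
        raise ValueError("counts must be >= 1")
    return n_records / (n_varieties * n_environments)


def _kinship(n_varieties: int, n_snps: int, rng) -> tuple[pd.DataFrame, np.ndarray]:
    gm = _simulate_genotypes(SynthConfig(n_varieties=n_varieties, n_snps=n_snps),
                             rng)
    G = vanraden_grm(gm)
    Gm = G.to_numpy() + 1e-6 * np.eye(n_varieties)
    L = np.linalg.cholesky(Gm) / np.sqrt(np.mean(np.diag(Gm)))
    return G, L


def h2_recovery_study(seed: int, n_varieties: int = 300, n_reps: int = 20,
                      n_records: int = 3, h2: float = 0.5,
                      n_snps: int = 2000) -> list[float]:
    """REML heritability estimates over replicate simulated trials.

    One environment, ``n_records`` replicate records per variety (the
    reference design has three years per environment), genetic variance 1
    and residual variance (1 - h2) / h2.
    """
    rng = stage_rng(seed, "h2_recovery")
    G, L = _kinship(n_varieties, n_snps, rng)
    ids = list(G.index)
    sigma_e = np.sqrt((1.0 - h2) / h2)
    out = []
    for _ in range(n_reps):
        u = L @ rng.normal(size=n_varieties)
        y = np.concatenate([3.0 + u + sigma_e * rng.normal(size=n_varieties)
                            for _ in range(n_records)])
        fit = fit_gblup(y, np.ones((n_records * n_varieties, 1)),
                        ids * n_records, G)
        out.append(fit.h2)
    return out


def rg_recovery_study(seed: int, n_varieties: int = 250, n_reps: int = 20,
                      r_g: float = 0.8, n_years: int = 2,
                      n_snps: int = 2000) -> list[float]:
    """Bivariate REML genetic-correlation estimates on paired trials."""
    rng = stage_rng(seed, "rg_recovery")
    G, L = _kinship(n_varieties, n_snps, rng)
    ids = list(G.index)
    Lu = np.linalg.cholesky(np.array([[1.0, r_g], [r_g, 1.0]]))
    out = []
    for _ in range(n_reps):
        U = L @ rng.normal(size=(n_varieties, 2)) @ Lu.T
        rows = []
        for t in range(n_years):
            Y = U + rng.normal(size=(n_varieties, 2))
            rows += [(ids[i], 2000 + t, Y[i, 0], Y[i, 1])
                     for i in range(n_varieties)]
        paired = pd.DataFrame(rows, columns=["variety_id", "year", "y_j", "y_k"])
        pc = fit_bivariate(paired, G, init=(1.0, 1.0, 1.0, 1.0))
        out.append(pc.r_g)
    return out


def end_to_end_study(seeds, sigma_beta2: float = 1.0) -> pd.DataFrame:
    """Run the full pipeline (through slopes) on one dataset per seed.

    Returns one row per seed with: whether the planted covariate was
    Bonferroni-significant, whether its cluster contributed a selected
    covariate, and the correlation of estimated slopes with the true ones
    (NaN when sigma_beta2 = 0).
    """
    from .pipeline import run_all

    rows = []
    for seed in seeds:
        cfg = SynthConfig(rng_seed=int(seed), sigma_beta2=sigma_beta2)
        gm, trials, weather, truth = generate_dataset(cfg)
        res = run_all(gm, trials, weather, ["yield"], cfg.run_config(),
                      with_gwas=False)
        t = res.scan.table.set_index("covariate_id")
        causal = truth.causal_covariate
        significant = bool(t.loc[causal, "significant"])
        cluster = t.loc[causal, "cluster_id"]
        detected = bool(((t["cluster_id"] == cluster) & t["selected"]).any())
        slope_corr = np.nan
        if sigma_beta2 > 0:
            slopes = estimate_slopes(res.fits["yield"], res.cov_table, causal)
            common = slopes.index.intersection(truth.beta.index)
            slope_corr = float(np.corrcoef(
                slopes.loc[common, "slope"], truth.beta.loc[common])[0, 1])
        rows.append({"seed": int(seed), "causal_significant": significant,
                     "cluster_detected": detected, "slope_corr": slope_corr})
        logger.info("end-to-end seed %d: significant=%s detected=%s slope_corr=%.3f",
                    seed, significant, detected, slope_corr)
    return pd.DataFrame(rows)
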