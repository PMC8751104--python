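"""Reaction-norm slopes, mixed-model GWAS, FDR, regions and subsampling.

For a detected covariate, each variety's sensitivity slope is the OLS
regression of its scaled additive genetic effects u^_vj / sigma_uj on the
standardised covariate values x_j across environments. Slopes are then the
phenotype of a P3D (EMMAX-style) mixed-model GWAS: variance components of
slope ~ N(mu, G sg^2 + I se^2) are fitted once without markers and every
marker is tested by generalised least squares. Significance is a Storey
q-value FDR threshold; significant SNPs under 100 kb apart chain into
regions, whose stability is checked by re-running the GWAS on random 80%
variety subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import eigh

from .io_config import GenotypeMatrix, RunConfig
from .mixed_models import GBLUPFit, fit_gblup

logger = logging.getLogger("ecgc")


# ---------------------------------------------------------------------------
# slopes


def estimate_slopes(fits: dict[str, GBLUPFit], cov_table: pd.DataFrame,
                    cov_id: str) -> pd.DataFrame:
    """Per-variety OLS slope of scaled additive effects on the covariate.

    Effects at environment j are scaled by the genetic SD sigma_uj (the
    reaction-norm decomposition u_j = sigma_uj (beta x_j + u~_j)); the
    covariate is standardised to mean 0, SD 1 across the environments
    used. Varieties need >= 2 environments with fits; with GBLUP all GRM
    varieties have predictions everywhere, so normally all are usable.
    Returns a DataFrame (index variety) with slope, intercept, n_env.
    """
    envs = [e for e in cov_table.index if e in fits]
    if len(envs) < 2:
        raise ValueError("need fits and covariate values for >= 2 environments")
    x = cov_table.loc[envs, cov_id].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"covariate {cov_id} constant across environments")
    xs = (x - x.mean()) / sd

    varieties = fits[envs[0]].u_hat.index
    Z = np.empty((len(varieties), len(envs)))
    for j, e in enumerate(envs):
        f = fits[e]
        s = np.sqrt(max(f.sigma_u2, 1e-10))
        Z[:, j] = f.u_hat.reindex(varieties).to_numpy() / s
    # OLS with intercept, shared regressor: slope_v = cov(xs, z_v) / var(xs)
    xc = xs - xs.mean()
    denom = float(xc @ xc)
    slopes = (Z @ xc) / denom
    intercepts = Z.mean(axis=1) - slopes * xs.mean()
    return pd.DataFrame({"slope": slopes, "intercept": intercepts,
                         "n_env": len(envs)}, index=varieties)


# ---------------------------------------------------------------------------
# mixed-model GWAS (P3D / EMMAX)


def mm_gwas(slopes: pd.Series, gm: GenotypeMatrix, grm: pd.DataFrame,
            maf_min: float = 0.05, tol: float = 1e-8,
            max_iter: int = 200) -> pd.DataFrame:
    """GWAS of slopes with a polygenic background, variance components fixed.

    Only SNPs with minor allele frequency strictly above ``maf_min`` in the
    analysed varieties are tested. No principal-component covariates are
    included. Markers collinear with the intercept get p = 1 and a
    ``degenerate`` flag.
    """
    ids = slopes.dropna().index.intersection(gm.doses.index).intersection(grm.index)
    y = slopes.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    if n < 50:
        raise ValueError(f"need >= 50 varieties with slopes, got {n}")
    X = gm.doses.loc[ids].to_numpy(dtype=float)
    p_freq = X.mean(axis=0) / 2.0
    maf = np.minimum(p_freq, 1 - p_freq)
    keep = maf > maf_min
    X = X[:, keep]
    snp_ids = gm.doses.columns[keep]
    snp_map = gm.snp_map.loc[snp_ids]
    G = grm.loc[ids, ids].to_numpy(dtype=float)

    # P3D: single REML fit without markers
    ones = np.ones((n, 1))
    fit = fit_gblup(y, ones, list(ids), grm.loc[ids, ids], tol=tol, max_iter=max_iter)
    lam = fit.sigma_u2 / max(fit.sigma_e2, 1e-12)

    d, U = eigh((G + G.T) / 2.0)
    w = 1.0 / (lam * np.clip(d, 0.0, None) + 1.0)
    yt = U.T @ y
    ot = U.T @ ones[:, 0]
    Mt = U.T @ X

    a11 = float(np.sum(w * ot * ot))
    b1 = float(np.sum(w * ot * yt))
    a12 = Mt.T @ (w * ot)
    a22 = np.einsum("is,is->s", Mt, w[:, None] * Mt)
    b2 = Mt.T @ (w * yt)
    yy = float(np.sum(w * yt * yt))

    det = a11 * a22 - a12**2
    degenerate = det <= 1e-10 * max(a11, 1.0) * np.maximum(a22, 1e-30)
    det_safe = np.where(degenerate, 1.0, det)
    beta_snp = (a11 * b2 - a12 * b1) / det_safe
    beta_int = (a22 * b1 - a12 * b2) / det_safe
    rss = yy - (beta_int * b1 + beta_snp * b2)
    df = n - 2
    sigma2 = np.clip(rss, 0.0, None) / df
    var_beta = sigma2 * a11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta_snp / np.sqrt(var_beta)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pvals = np.where(degenerate, 1.0, pvals)
    beta_snp = np.where(degenerate, 0.0, beta_snp)

    out = pd.DataFrame({
        "snp": snp_ids,
        "chrom": snp_map["chrom"].to_numpy(),
        "bp": snp_map["bp"].to_numpy(),
        "maf": maf[keep],
        "beta": beta_snp,
        "p": np.clip(pvals, 1e-300, 1.0),
        "degenerate": degenerate,
    })
    out["neg_log10_p"] = -np.log10(out["p"])
    return out


# ---------------------------------------------------------------------------
# Storey FDR


def storey_qvalues(pvals: np.ndarray, lambdas: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-extrapolated pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a 0.05..0.90 grid,
    extrapolated to lambda -> max by a cubic polynomial smoother and
    clipped to (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.9001, 0.05)
    pi0_l = np.array([np.mean(p > lam) / (1 - lam) for lam in lambdas])
    if m < 100:
        pi0 = 1.0  # too few tests for the smoother; fall back to BH-style pi0
    else:
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    pi0 = min(pi0, 1.0)
    pi0 = max(pi0, 1e-8)  # keep strictly positive

    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, pi0


def fdr_threshold(pvals: np.ndarray, fdr_level: float = 0.05) -> float | None:
    """Largest p whose Storey q-value is <= fdr_level, or None."""
    p = np.asarray(pvals, dtype=float)
    q, _ = storey_qvalues(p)
    ok = p[q <= fdr_level]
    return float(ok.max()) if ok.size else None


# ---------------------------------------------------------------------------
# regions


@dataclass
class Region:
    chrom: str
    start_bp: int
    end_bp: int
    snps: list[str]
    best_neg_log10_p: float
    subsample_count: int | None = None
    reliable: bool | None = None


def group_regions(sig_snps: pd.DataFrame, region_gap_bp: int = 100_000) -> list[Region]:
    """Chain significant SNPs less than region_gap_bp apart (strict).

    ``sig_snps`` needs columns snp, chrom, bp, neg_log10_p. Order of the
    input does not matter; output regions are sorted by (chrom, start).
    """
    regions: list[Region] = []
    if sig_snps.empty:
        return regions
    df = sig_snps.sort_values(["chrom", "bp"], kind="mergesort")
    cur: list[tuple] = []

    def flush():
        if cur:
            regions.append(Region(
                chrom=str(cur[0][0]), start_bp=int(cur[0][1]), end_bp=int(cur[-1][1]),
                snps=[c[2] for c in cur],
                best_neg_log10_p=float(max(c[3] for c in cur))))

    prev_chrom, prev_bp = None, None
    for r in df.itertuples(index=False):
        same = (r.chrom == prev_chrom) and prev_bp is not None and (r.bp - prev_bp) < region_gap_bp
        if not same:
            flush()
            cur = []
        cur.append((r.chrom, r.bp, r.snp, r.neg_log10_p))
        prev_chrom, prev_bp = r.chrom, r.bp
    flush()
    return regions


def subsample_validate(slopes: pd.Series, gm: GenotypeMatrix, grm: pd.DataFrame,
                       regions: list[Region], full_threshold_p: float,
                       config: RunConfig, rng: np.random.Generator) -> list[Region]:
    """Count, per region, subsampled GWAS runs reproducing the association.

    Each of ``config.subsample_reps`` replicates draws
    floor(subsample_fraction * n) varieties without replacement, reruns the
    GWAS, and scores a region as hit when any member SNP reaches the
    full-data FDR p threshold. Regions with count >= subsample_min_count
    ("more than 4" under the defaults) are flagged reliable.
    """
    ids = slopes.dropna().index.intersection(gm.doses.index).intersection(grm.index)
    n_draw = int(np.floor(config.subsample_fraction * len(ids)))
    counts = np.zeros(len(regions), dtype=int)
    for _ in range(config.subsample_reps):
        sub = pd.Index(rng.choice(ids.to_numpy(), size=n_draw, replace=False))
        res = mm_gwas(slopes.loc[sub], gm, grm, maf_min=config.maf_min,
                      tol=config.reml_tol, max_iter=config.reml_max_iter)
        hit_p = res.set_index("snp")["p"]
        for i, reg in enumerate(regions):
            ps = hit_p.reindex(reg.snps).dropna()
            if len(ps) and (ps <= full_threshold_p).any():
                counts[i] += 1
    out = []
    for reg, c in zip(regions, counts):
        out.append(Region(chrom=reg.chrom, start_bp=reg.start_bp, end_bp=reg.end_bp,
                          snps=list(reg.snps), best_neg_log10_p=reg.best_neg_log10_p,
                          subsample_count=int(c),
                          reliable=bool(c >= config.subsample_min_count)))
    return out


# ---------------------------------------------------------------------------
# selection-history trend


def selection_trend(slopes: pd.Series, cov_table: pd.DataFrame, cov_id: str,
                    record_counts: pd.DataFrame) -> tuple[float, float]:
    """Correlation of a covariate with per-environment mean slopes.

    ``record_counts`` is environments x varieties (records of each variety
    at each environment; 0 = not evaluated). The per-environment summary is
    the record-count-weighted mean slope of the varieties evaluated there.
    Returns Pearson (r, p); degenerate (constant) inputs give (nan, 1).
    """
    envs = [e for e in cov_table.index if e in record_counts.index]
    if len(envs) < 4:
        raise ValueError("need >= 4 environments")
    x = cov_table.loc[envs, cov_id].to_numpy(dtype=float)
    w_means = []
    for e in envs:
        cnt = record_counts.loc[e].reindex(slopes.index).fillna(0.0)
        mask = (cnt > 0) & slopes.notna()
        if not mask.any():
            w_means.append(np.nan)
            continue
        w = cnt[mask].to_numpy(dtype=float)
        w_means.append(float(np.average(slopes[mask].to_numpy(dtype=float), weights=w)))
    m = np.asarray(w_means)
    ok = np.isfinite(m)
    if ok.sum() < 4 or np.std(m[ok]) == 0 or np.std(x[ok]) == 0:
        return float("nan"), 1.0
    res = stats.pearsonr(x[ok], m[ok])
    return float(res.statistic), float(res.pvalue)
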