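"""Covariate scan: correlate similarity with genetic-correlation matrices.

For every stage-window covariate, the Pearson correlation r between the
upper-triangle off-diagonals of its similarity matrix and of the genetic
correlation matrix is computed; r^2 is the fraction of genetic-correlation
variance attributable to the covariate. Significance is Bonferroni over
(covariates x traits). Because neighbouring windows are strongly
redundant, covariates are grouped by complete-linkage hierarchical
clustering (gap statistic for the cluster count) and only the top-r^2
significant covariate per cluster is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist

from .env_covariates import parse_covariate_id

logger = logging.getLogger("ecgc")


def offdiag(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle off-diagonal entries, row-major order."""
    mat = np.asarray(mat, dtype=float)
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def correlate_offdiag(similarity: np.ndarray, gen_corr: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-test p over the matrices' off-diagonals.

    Degenerate inputs (zero variance in either vector, e.g. a constant
    covariate) return (nan, 1.0).
    """
    similarity = np.asarray(similarity, dtype=float)
    gen_corr = np.asarray(gen_corr, dtype=float)
    if similarity.shape != gen_corr.shape or similarity.shape[0] < 4:
        raise ValueError("need two equal-shape square matrices with M >= 4")
    a, b = offdiag(similarity), offdiag(gen_corr)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), 1.0
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(n_covariates: int, n_traits: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / (covariates x traits)."""
    if n_covariates < 1 or n_traits < 1:
        raise ValueError("counts must be >= 1")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return alpha / (n_covariates * n_traits)


# ---------------------------------------------------------------------------
# gap-statistic clustering


def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """log W_k: summed within-cluster mean pairwise squared distance / 2."""
    W = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        if len(pts) > 1:
            W += float(np.sum(pdist(pts, metric="sqeuclidean"))) / (2 * len(pts))
    return np.log(max(W, 1e-300))


def _hclust_labels(X: np.ndarray, max_k: int) -> list[np.ndarray]:
    link = linkage(X, method="complete", metric="euclidean")
    cuts = cut_tree(link, n_clusters=list(range(1, max_k + 1)))
    return [cuts[:, i] for i in range(max_k)]


def gap_statistic(X: np.ndarray, max_k: int, b_ref: int,
                  rng: np.random.Generator) -> tuple[int, pd.DataFrame]:
    """Gap-statistic choice of k for complete-linkage hierarchical clustering.

    Reference datasets are uniform over the feature bounding box; k is
    picked with the first-SE-max rule (smallest k whose gap is within one
    standard error of the first local maximum of the gap curve).
    """
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    n = X.shape[0]
    max_k = min(max_k, n)
    labels_per_k = _hclust_labels(X, max_k)
    log_w = np.array([_pooled_within_dispersion(X, lab) for lab in labels_per_k])

    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_log_w = np.empty((b_ref, max_k))
    for b in range(b_ref):
        R = rng.uniform(lo, hi, size=X.shape)
        for i, lab in enumerate(_hclust_labels(R, max_k)):
            ref_log_w[b, i] = _pooled_within_dispersion(R, lab)
    gap = ref_log_w.mean(axis=0) - log_w
    se = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b_ref)

    # first local maximum of the gap curve, then first k within 1 SE of it
    k_star = max_k - 1
    for i in range(max_k - 1):
        if gap[i] >= gap[i + 1]:
            k_star = i
            break
    k_hat = 1 + int(np.argmax(gap[:k_star + 1] >= gap[k_star] - se[k_star]))
    table = pd.DataFrame({"k": np.arange(1, max_k + 1), "log_w": log_w,
                          "gap": gap, "se": se})
    return k_hat, table


def cluster_covariates(cov_table: pd.DataFrame, max_k: int | None = None,
                       b_ref: int = 50,
                       rng: np.random.Generator | None = None) -> pd.Series:
    """Cluster covariates on their standardised environment-value vectors.

    Each covariate is a point in R^M (one coordinate per environment),
    standardised to zero mean / unit variance across environments so
    clusters group covariates with near-identical similarity kernels.
    Returns integer labels (1..k) indexed by covariate id.
    """
    if cov_table.shape[1] < 2:
        raise ValueError("need at least 2 covariates to cluster")
    if rng is None:
        rng = np.random.default_rng(0)
    X = cov_table.to_numpy(dtype=float).T  # covariates x environments
    sd = X.std(axis=1, ddof=0)
    mu = X.mean(axis=1)
    sd[sd == 0] = 1.0
    Xs = (X - mu[:, None]) / sd[:, None]
    if max_k is None:
        max_k = min(50, Xs.shape[0] - 1)
    k_hat, _ = gap_statistic(Xs, max_k=max_k, b_ref=b_ref, rng=rng)
    labels = _hclust_labels(Xs, max(k_hat, 1))[k_hat - 1] + 1
    return pd.Series(labels, index=cov_table.columns, name="cluster_id")


# ---------------------------------------------------------------------------
# scan + pruning


@dataclass
class ScanResult:
    table: pd.DataFrame  # per (trait, covariate) rows
    threshold: float


def scan_covariates(cov_table: pd.DataFrame, gen_corr: dict[str, pd.DataFrame],
                    alpha: float = 0.05,
                    cluster_labels: pd.Series | None = None,
                    n_covariates_total: int | None = None) -> ScanResult:
    """Full covariate scan over one or more traits.

    ``gen_corr`` maps trait name -> genetic correlation matrix (environments
    matching ``cov_table``). ``n_covariates_total`` overrides the Bonferroni
    family size (defaults to covariates in the table x traits).
    """
    n_cov = n_covariates_total or cov_table.shape[1]
    threshold = bonferroni_threshold(n_cov, len(gen_corr), alpha)
    rows = []
    for trait, P in gen_corr.items():
        envs = [e for e in cov_table.index if e in P.index]
        Pm = P.loc[envs, envs].to_numpy(dtype=float)
        sub = cov_table.loc[envs]
        for cov_id in cov_table.columns:
            x = sub[cov_id].to_numpy(dtype=float)
            xc = x - x.mean()
            r, p = correlate_offdiag(np.outer(xc, xc), Pm)
            rows.append({"trait": trait, "covariate_id": cov_id, "r": r,
                         "r2": r * r if np.isfinite(r) else np.nan,
                         "p": p,
                         "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                         "significant": bool(p < threshold)})
    table = pd.DataFrame(rows)
    if cluster_labels is not None:
        table["cluster_id"] = table["covariate_id"].map(cluster_labels).astype(int)
        table = prune_significant(table)
    return ScanResult(table=table, threshold=threshold)


def prune_significant(scan_table: pd.DataFrame) -> pd.DataFrame:
    """Mark, per (trait, cluster), the max-r^2 significant covariate.

    Exact r^2 ties break deterministically towards the earliest window
    (smallest start stage, end stage, then factor order).
    """
    out = scan_table.copy()
    out["selected"] = False

    def sort_key(cov_id: str):
        fac, a, b = parse_covariate_id(cov_id)
        return (a, b, fac)

    for (_, _), grp in out.groupby(["trait", "cluster_id"], sort=False):
        sig = grp[grp["significant"] & grp["r2"].notna()]
        if sig.empty:
            continue
        best_r2 = sig["r2"].max()
        ties = sig[sig["r2"] == best_r2]
        winner = min(ties.index, key=lambda i: sort_key(out.loc[i, "covariate_id"]))
        out.loc[winner, "selected"] = True
    return out
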