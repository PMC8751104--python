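"""Power study: planted covariate signal + LKJ noise in correlation matrices.

Each replicate plants a covariate x ~ N(0, I_M) into a genetic correlation
matrix as P_jk = x_j x_k + sigma_jk, where the noise sigma_jk comes from an
LKJ(eta) correlation-matrix draw rescaled so that the off-diagonal variance
ratio var(x_j x_k) / var(P_jk) equals the target r^2. The covariate scan's
off-diagonal Pearson test is then applied to the true covariate and to 99
independent standard-normal decoys, and detection is scored with pooled ROC
curves / AUC across replicates. The simplifications fixed throughout are
zero covariate-residual cross-covariance, unit genetic variances, and unit
slope variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .io_config import stage_rng
from .mixed_models import near_pd

R2_GRID_FULL = (0.01, 0.018, 0.025, 0.035, 0.053, 0.075, 0.1, 0.15)
M_GRID_FULL = (5, 10, 15, 20, 30, 40, 50, 60)


@dataclass
class SimConfig:
    """Grid and distribution settings of the power study."""

    r2_grid: tuple[float, ...] = R2_GRID_FULL
    m_grid: tuple[int, ...] = M_GRID_FULL
    eta: float = 4.0
    reps: int = 200          # desk default; full-scale studies use 2000
    n_negatives: int = 99
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.r2_grid) <= 0 or max(self.r2_grid) >= 1:
            raise ValueError("r2 grid values must be in (0, 1)")
        if min(self.m_grid) < 2:
            raise ValueError("M grid values must be >= 2")
        if self.eta <= 0 or self.reps < 1:
            raise ValueError("eta > 0 and reps >= 1 required")


def sample_lkj(M: int, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a correlation matrix from the LKJ(eta) distribution (onion method).

    For M = 2 the single correlation is 2 Beta(eta, eta) - 1, with variance
    1 / (2 eta + 1).
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if eta <= 0:
        raise ValueError("eta must be > 0")
    beta = eta + (M - 2) / 2.0
    r12 = 2.0 * rng.beta(beta, beta) - 1.0
    R = np.array([[1.0, r12], [r12, 1.0]])
    for k in range(2, M):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        u = rng.normal(size=k)
        u /= np.linalg.norm(u)
        w = np.sqrt(y) * u
        A = np.linalg.cholesky(R + 1e-14 * np.eye(k))
        z = A @ w
        R = np.block([[R, z[:, None]], [z[None, :], np.array([[1.0]])]])
    return (R + R.T) / 2.0


def simulate_corr_matrix(r2: float, M: int, eta: float,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One planted-signal genetic correlation matrix and its covariate.

    The LKJ noise off-diagonals are rescaled so that, in realised terms,
    var(sigma_jk) = var(x_j x_k) (1 - r2) / r2 over the M(M-1)/2 pairs;
    the diagonal of the raw signal matrix is set to the mean of x_j^2
    before standardising to a correlation matrix.
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    x = rng.normal(size=M)
    iu = np.triu_indices(M, k=1)
    xx = np.outer(x, x)
    var_xx = float(np.var(xx[iu], ddof=1))
    noise = sample_lkj(M, eta, rng)
    var_noise = float(np.var(noise[iu], ddof=1))
    target = var_xx * (1.0 - r2) / r2
    scale = np.sqrt(target / var_noise) if var_noise > 0 else 0.0
    S = xx + scale * noise
    np.fill_diagonal(S, np.mean(x**2))
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    P = S / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    w = np.linalg.eigvalsh((P + P.T) / 2.0)
    if w[0] <= 0:
        P = near_pd(P, corr=True)
    return (P + P.T) / 2.0, x


def _offdiag_corr_pvalues(P: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Vectorised off-diagonal Pearson p-values of each covariate row of X."""
    M = P.shape[0]
    iu = np.triu_indices(M, k=1)
    b = P[iu]
    bc = b - b.mean()
    nb = np.sqrt(bc @ bc)
    Xc = X - X.mean(axis=1, keepdims=True)
    A = Xc[:, iu[0]] * Xc[:, iu[1]]  # similarity off-diagonals per covariate
    Ac = A - A.mean(axis=1, keepdims=True)
    na = np.sqrt(np.sum(Ac**2, axis=1))
    na[na == 0] = np.inf
    r = (Ac @ bc) / (na * nb)
    n = len(b)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def power_cell(r2: float, M: int, config: SimConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (labels, -log10 p scores) over all replicates of one cell."""
    labels, scores = [], []
    for _ in range(config.reps):
        P, x = simulate_corr_matrix(r2, M, config.eta, rng)
        X = np.vstack([x, rng.normal(size=(config.n_negatives, M))])
        p = _offdiag_corr_pvalues(P, X)
        p = np.clip(p, 1e-300, 1.0)
        scores.append(-np.log10(p))
        labels.append(np.concatenate([[1], np.zeros(config.n_negatives, dtype=int)]))
    return np.concatenate(labels), np.concatenate(scores)


def run_power_study(config: SimConfig) -> pd.DataFrame:
    """ROC/AUC table over the (r2, M) grid.

    One row per grid cell with the pooled AUC and the pooled ROC curve
    (FPR/TPR arrays), labels and scores pooled across replicates.
    """
    rows = []
    for r2 in config.r2_grid:
        for M in config.m_grid:
            rng = stage_rng(config.rng_seed, f"power_r2={r2}_M={M}")
            labels, scores = power_cell(r2, M, config, rng)
            fpr, tpr, _ = roc_curve(labels, scores)
            auc = float(roc_auc_score(labels, scores))
            rows.append({"r2": r2, "M": M, "auc": auc,
                         "fpr": fpr, "tpr": tpr,
                         "n_pos": int(labels.sum()), "n_neg": int((1 - labels).sum())})
    return pd.DataFrame(rows)


def auc_table(roc: pd.DataFrame) -> pd.DataFrame:
    """AUC pivot (rows r2, columns M) from run_power_study output."""
    return roc.pivot(index="r2", columns="M", values="auc")
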