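"""Per-environment GBLUP and pairwise bivariate REML genetic correlations.

Single-trait model (one environment j, one trait):

    y = X b + Z u + e,   u ~ N(0, G sigma_u^2),   e ~ N(0, I sigma_e^2)

fitted by exact REML: after absorbing the fixed effects the likelihood
profiles to a single variance ratio, optimised by Brent's method on the
spectrum of the projected kinship. The adjusted phenotypes y~ = y - X b
feed the bivariate step and the BLUPs u^ feed the reaction-norm slopes.

Bivariate model (environments j, k treated as two traits):

    [y~_j; y~_k] = [Z_j 0; 0 Z_k][u_j; u_k] + [e_j; e_k]

with cov([u_j; u_k]) = Sigma_u (x) G and residuals independent across
(variety, year) rows; rows observed in both environments share a 2x2
residual covariance Sigma_e, rows observed in one contribute the marginal
residual variance only. The REML (= ML, the inputs are already adjusted
for fixed effects) likelihood is maximised directly over the Cholesky
factors of Sigma_u and Sigma_e. A canonical decomposition — simultaneous
diagonalisation of G and the complete-row replication pattern, plus a
low-rank Woodbury correction for the single-environment rows — makes each
likelihood evaluation O(q) in the number of varieties, which keeps the
M(M-1)/2 pairwise fits tractable.

The per-pair estimates are assembled into an M x M genetic covariance
matrix (diagonal = mean of the M-1 per-pair variance estimates), repaired
to positive definiteness with Higham's alternating projections, and
standardised to a correlation matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, eigh

logger = logging.getLogger("ecgc")

_VAR_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# single-trait GBLUP


@dataclass
class GBLUPFit:
    """REML fit of a single-trait GBLUP at one environment."""

    sigma_u2: float
    sigma_e2: float
    beta: np.ndarray
    u_hat: pd.Series  # indexed by every variety in the GRM
    y_adj: np.ndarray  # y - X beta, per record
    environment_id: str | None = None
    trait: str | None = None
    records: pd.DataFrame | None = None  # (variety_id, year, y_adj), set by the pipeline

    @property
    def h2(self) -> float:
        return self.sigma_u2 / max(self.sigma_u2 + self.sigma_e2, _VAR_FLOOR)


def _drop_aliased(X: np.ndarray) -> np.ndarray:
    """Keep a full-column-rank subset of X (QR with column pivoting)."""
    if X.ndim != 2:
        raise ValueError("fixed design must be 2-D")
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        if len(keep) == rank:
            break
    return X[:, keep]


def _kin_factor(G: np.ndarray) -> np.ndarray:
    """Symmetric factor L with LL' = G (eigenvalues clipped at 0)."""
    w, V = eigh((G + G.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def fit_gblup(y: np.ndarray, X: np.ndarray, variety_ids, grm: pd.DataFrame,
              tol: float = 1e-8, max_iter: int = 200,
              environment_id: str | None = None, trait: str | None = None) -> GBLUPFit:
    """Exact single-ratio REML GBLUP fit.

    variety_ids maps each record to a row of ``grm``; BLUPs are predicted
    for every variety in the GRM (through G), observed or not.
    """
    y = np.asarray(y, dtype=float)
    X = _drop_aliased(np.asarray(X, dtype=float))
    n, p = X.shape
    if n != len(y):
        raise ValueError("y and X row counts differ")
    obs_vars = pd.Index(pd.unique(pd.Series(variety_ids)))
    if len(obs_vars) < 2:
        raise ValueError("need records on >= 2 varieties")
    ridx = obs_vars.get_indexer(pd.Series(variety_ids))
    G_oo = grm.loc[obs_vars, obs_vars].to_numpy(dtype=float)
    q = len(obs_vars)

    L = _kin_factor(G_oo)
    B = L[ridx, :]  # n x q, row per record
    # project out fixed effects: A = (I - X (X'X)^-1 X') B
    coefB, *_ = np.linalg.lstsq(X, B, rcond=None)
    A = B - X @ coefB
    coefy, *_ = np.linalg.lstsq(X, y, rcond=None)
    ys = y - X @ coefy

    AtA = A.T @ A
    theta, V = eigh(AtA)
    keep = theta > max(theta[-1], 1.0) * 1e-12
    theta = theta[keep]
    U = A @ (V[:, keep] / np.sqrt(theta))
    eta = U.T @ ys
    sse_null = float(ys @ ys - eta @ eta)  # zero-eigenvalue directions
    df = n - p
    if df <= len(theta):
        sse_null = max(sse_null, 0.0)

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        xi = lam * theta + 1.0
        rss = float(np.sum(eta**2 / xi) + sse_null)
        return df * np.log(rss) + float(np.sum(np.log(xi)))

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-25.0, 25.0),
                                   method="bounded",
                                   options={"xatol": tol, "maxiter": max_iter})
    if not res.success:
        raise RuntimeError(f"single-trait REML did not converge: lambda={np.exp(res.x):.3g}")
    lam = float(np.exp(res.x))
    xi = lam * theta + 1.0
    sigma_e2 = float((np.sum(eta**2 / xi) + sse_null) / df)
    sigma_u2 = lam * sigma_e2
    sigma_e2 = max(sigma_e2, _VAR_FLOOR)
    sigma_u2 = max(sigma_u2, 0.0)

    # GLS fixed effects and BLUPs via Woodbury on V = sigma_e2 (lam B B' + I)
    def v_solve(z: np.ndarray) -> np.ndarray:
        # returns V^{-1} z
        mid = np.eye(q) / lam + B.T @ B if lam > 0 else None
        if lam <= 0:
            return z / sigma_e2
        c = cho_factor((mid + mid.T) / 2.0)
        return (z - B @ cho_solve(c, B.T @ z)) / sigma_e2

    Vi_X = v_solve(X)
    XtViX = X.T @ Vi_X
    try:
        cfac = cho_factor((XtViX + XtViX.T) / 2.0)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("negative-definite GLS system for fixed effects") from exc
    beta = cho_solve(cfac, Vi_X.T @ y)
    resid = y - X @ beta
    w = v_solve(resid)
    t = np.zeros(q)
    np.add.at(t, ridx, w)
    u_all = sigma_u2 * (grm.loc[:, obs_vars].to_numpy(dtype=float) @ t)
    u_hat = pd.Series(u_all, index=grm.index, name="u_hat")
    return GBLUPFit(sigma_u2=sigma_u2, sigma_e2=sigma_e2, beta=beta, u_hat=u_hat,
                    y_adj=resid, environment_id=environment_id, trait=trait)


# ---------------------------------------------------------------------------
# record matching


def match_records(recs_j: pd.DataFrame, recs_k: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Pair adjusted records of two environments by (variety, year).

    Each input has columns variety_id, year, value. When several records
    share a (variety, year) key on one side, the pairing among candidates
    is drawn uniformly with ``rng``; leftovers become rows with the partner
    missing. Output columns: variety_id, year, y_j, y_k.
    """
    def groups(df):
        out: dict[tuple, list[float]] = {}
        for r in df.itertuples(index=False):
            out.setdefault((r.variety_id, r.year), []).append(float(r.value))
        return out

    gj, gk = groups(recs_j), groups(recs_k)
    rows = []
    for key in sorted(set(gj) | set(gk), key=lambda k: (str(k[0]), str(k[1]))):
        a = list(gj.get(key, []))
        b = list(gk.get(key, []))
        if len(a) > 1:
            rng.shuffle(a)
        if len(b) > 1:
            rng.shuffle(b)
        for i in range(max(len(a), len(b))):
            rows.append((key[0], key[1],
                         a[i] if i < len(a) else np.nan,
                         b[i] if i < len(b) else np.nan))
    return pd.DataFrame(rows, columns=["variety_id", "year", "y_j", "y_k"])


# ---------------------------------------------------------------------------
# bivariate REML


@dataclass
class PairwiseCovariance:
    """Estimated 2x2 genetic and residual covariance of one environment pair."""

    env_j: str
    env_k: str
    sigma_u: np.ndarray  # 2x2
    sigma_e: np.ndarray  # 2x2
    converged: bool = True
    n_complete: int = 0

    @property
    def r_g(self) -> float:
        d = np.sqrt(max(self.sigma_u[0, 0], _VAR_FLOOR) * max(self.sigma_u[1, 1], _VAR_FLOOR))
        return float(self.sigma_u[0, 1] / d)


def _chol2(l11: float, l21: float, l22: float) -> np.ndarray:
    L = np.array([[np.exp(l11), 0.0], [l21, np.exp(l22)]])
    return L @ L.T


class _BivariateREML:
    """Likelihood engine for one environment pair (see module docstring)."""

    def __init__(self, paired: pd.DataFrame, grm: pd.DataFrame, jitter: float = 1e-6):
        both = paired["y_j"].notna() & paired["y_k"].notna()
        only_j = paired["y_j"].notna() & paired["y_k"].isna()
        only_k = paired["y_k"].notna() & paired["y_j"].isna()
        used = paired[both | only_j | only_k]
        vars_ = pd.Index(pd.unique(used["variety_id"]))
        if len(vars_) < 3:
            raise ValueError("need >= 3 varieties linking the pair")
        self.vars_ = vars_
        q = len(vars_)
        vidx = vars_.get_indexer(used["variety_id"])

        comp = used[both.loc[used.index]]
        ci = vars_.get_indexer(comp["variety_id"])
        self.m = np.zeros(q)
        np.add.at(self.m, ci, 1.0)
        self.sum_y = np.zeros((q, 2))
        np.add.at(self.sum_y, ci, comp[["y_j", "y_k"]].to_numpy(dtype=float))
        Yc = comp[["y_j", "y_k"]].to_numpy(dtype=float)
        self.S2 = Yc.T @ Yc if len(Yc) else np.zeros((2, 2))
        self.n_complete = len(comp)

        # single-environment cells: per (trait, variety) counts / sums / ssq
        self.singles = []  # list of (trait, variety_row, count, sum)
        self.ssq = np.zeros(2)
        for t, col, mask in ((0, "y_j", only_j), (1, "y_k", only_k)):
            sub = used[mask.loc[used.index]]
            if not len(sub):
                continue
            si = vars_.get_indexer(sub["variety_id"])
            vals = sub[col].to_numpy(dtype=float)
            self.ssq[t] += float(vals @ vals)
            cnt = np.zeros(q)
            ssum = np.zeros(q)
            np.add.at(cnt, si, 1.0)
            np.add.at(ssum, si, vals)
            for v in np.nonzero(cnt)[0]:
                self.singles.append((t, int(v), cnt[v], ssum[v]))
        self.n_obs = self.n_complete * 2 + sum(int(c) for _, _, c, _ in self.singles)

        G = grm.loc[vars_, vars_].to_numpy(dtype=float)
        G = (G + G.T) / 2.0 + jitter * np.eye(q)
        Lg = np.linalg.cholesky(G)
        H = Lg.T @ (self.m[:, None] * Lg)
        lam, Q = eigh((H + H.T) / 2.0)
        self.lam = np.clip(lam, 0.0, None)
        self.P = Lg @ Q  # q x q; u = P w
        self.q = q

        # rotated single vectors and single sums
        if self.singles:
            rows = np.array([v for _, v, _, _ in self.singles])
            self.Ps = self.P[rows, :]  # s x q
            self.s_trait = np.array([t for t, _, _, _ in self.singles])
            self.s_cnt = np.array([c for _, _, c, _ in self.singles])
            self.s_sum = np.array([s for _, _, _, s in self.singles])
        else:
            self.Ps = np.zeros((0, q))
            self.s_trait = np.zeros(0, dtype=int)
            self.s_cnt = np.zeros(0)
            self.s_sum = np.zeros(0)

    def neg2ll(self, sigma_u: np.ndarray, sigma_e: np.ndarray) -> float:
        q = self.q
        try:
            iu = np.linalg.inv(sigma_u)
            E = np.linalg.inv(sigma_e)
        except np.linalg.LinAlgError:
            return np.inf
        det_u = np.linalg.det(sigma_u)
        det_e = np.linalg.det(sigma_e)
        if det_u <= 0 or det_e <= 0 or sigma_e[0, 0] <= 0 or sigma_e[1, 1] <= 0:
            return np.inf

        # ln|R| and y'R^{-1}y
        ln_R = self.n_complete * np.log(det_e)
        ytRy = float(np.sum(E * self.S2))
        for t in (0, 1):
            n_t = float(np.sum(self.s_cnt[self.s_trait == t]))
            if n_t:
                ln_R += n_t * np.log(sigma_e[t, t])
            ytRy += self.ssq[t] / sigma_e[t, t]

        # b = Z'R^{-1}y in variety space, then rotate by P'
        b = self.sum_y @ E.T  # q x 2 : b[:, a] = sum_b E[a,b] sum_y[:, b]
        for (t, v, _, ssum) in self.singles:
            b[v, t] += ssum / sigma_e[t, t]
        bt = self.P.T @ b  # q x 2 rotated, column per trait

        # base blocks per eigenvalue: K_i = iu + lam_i E  (2x2)
        k11 = iu[0, 0] + self.lam * E[0, 0]
        k12 = iu[0, 1] + self.lam * E[0, 1]
        k22 = iu[1, 1] + self.lam * E[1, 1]
        det_k = k11 * k22 - k12 * k12
        if np.any(det_k <= 0):
            return np.inf
        ln_B = float(np.sum(np.log(det_k)))
        # B^{-1} entries per i
        i11, i12, i22 = k22 / det_k, -k12 / det_k, k11 / det_k

        # z = B^{-1} bt
        z0 = i11 * bt[:, 0] + i12 * bt[:, 1]
        z1 = i12 * bt[:, 0] + i22 * bt[:, 1]
        quad = float(bt[:, 0] @ z0 + bt[:, 1] @ z1)
        ln_C = ln_B

        s = len(self.singles)
        if s:
            w = self.s_cnt / sigma_e[self.s_trait, self.s_trait]
            # M_cap = diag(1/w) + U' B^{-1} U with
            # (U'B^{-1}U)_{rs} = sum_i Ps[r,i] Binv[t_r,t_s]_i Ps[s,i]
            def cross(tr, ts):
                if tr == ts:
                    return i11 if tr == 0 else i22
                return i12
            M_cap = np.empty((s, s))
            for r in range(s):
                row0 = (self.Ps[r] * cross(self.s_trait[r], 0)) @ self.Ps.T
                row1 = (self.Ps[r] * cross(self.s_trait[r], 1)) @ self.Ps.T
                M_cap[r] = np.where(self.s_trait == 0, row0, row1)
            M_cap[np.arange(s), np.arange(s)] += 1.0 / w
            # v = U' z
            v = np.where(self.s_trait == 0, self.Ps @ z0, self.Ps @ z1)
            try:
                cfac = cho_factor((M_cap + M_cap.T) / 2.0)
            except np.linalg.LinAlgError:
                return np.inf
            quad -= float(v @ cho_solve(cfac, v))
            ln_C += 2.0 * float(np.sum(np.log(np.diag(cfac[0])))) + float(np.sum(np.log(w)))

        ln_V = ln_R + q * np.log(det_u) + ln_C
        return float(self.n_obs * np.log(2 * np.pi) + ln_V + ytRy - quad)


def fit_bivariate(paired: pd.DataFrame, grm: pd.DataFrame,
                  tol: float = 1e-8, max_iter: int = 200,
                  env_j: str = "j", env_k: str = "k",
                  init: tuple[float, float, float, float] | None = None) -> PairwiseCovariance:
    """REML estimates of the 2x2 genetic / residual covariance of a pair.

    ``paired`` comes from :func:`match_records`. The residual covariance is
    estimated only when at least one (variety, year) row is observed in
    both environments, and fixed at 0 otherwise. ``init`` optionally seeds
    the optimiser with (sigma_u2_j, sigma_e2_j, sigma_u2_k, sigma_e2_k)
    from the single-trait fits.
    """
    eng = _BivariateREML(paired, grm)
    est_res_cov = eng.n_complete >= 2

    if init is None:
        vj = np.nanvar(paired["y_j"].to_numpy(dtype=float))
        vk = np.nanvar(paired["y_k"].to_numpy(dtype=float))
        init = (max(vj, 1e-4) / 2, max(vj, 1e-4) / 2, max(vk, 1e-4) / 2, max(vk, 1e-4) / 2)
    su_j, se_j, su_k, se_k = (max(v, 1e-8) for v in init)

    x0 = [0.5 * np.log(su_j), 0.0, 0.5 * np.log(su_k),
          0.5 * np.log(se_j), 0.5 * np.log(se_k)]
    if est_res_cov:
        x0.insert(4, 0.0)  # residual cross term

    def unpack(x):
        if est_res_cov:
            lu11, lu21, lu22, le11, le21, le22 = x
        else:
            lu11, lu21, lu22, le11, le22 = x
            le21 = 0.0
        # guard against runaway Cholesky entries
        if max(abs(lu11), abs(lu22), abs(le11), abs(le22)) > 20 or max(abs(lu21), abs(le21)) > 1e4:
            return None, None
        return _chol2(lu11, lu21, lu22), _chol2(le11, le21, le22)

    def obj(x):
        su, se = unpack(x)
        if su is None:
            return 1e12
        val = eng.neg2ll(su, se)
        return val if np.isfinite(val) else 1e12

    # quasi-Newton with numerical gradients; Nelder-Mead fallback for the
    # occasional boundary case (e.g. near-singular Sigma_u)
    res = optimize.minimize(obj, x0, method="L-BFGS-B",
                            options={"ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6,
                                     "maxiter": max_iter * 5})
    if not res.success:
        res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-6, "fatol": 1e-8,
                                          "maxiter": 4000, "maxfev": 4000})
        if res2.fun <= res.fun:
            res = res2
    su, se = unpack(res.x)
    converged = bool(res.success) and su is not None
    if su is None:
        su = np.diag([su_j, su_k])
        se = np.diag([se_j, se_k])
    return PairwiseCovariance(env_j=env_j, env_k=env_k, sigma_u=su, sigma_e=se,
                              converged=converged, n_complete=eng.n_complete)


# ---------------------------------------------------------------------------
# nearest positive definite matrix (Higham)


def near_pd(A: np.ndarray, eig_tol: float = 1e-8, corr: bool = False,
            max_iter: int = 100, conv_tol: float = 1e-9) -> np.ndarray:
    """Nearest positive semi-definite matrix by alternating projections.

    Higham's algorithm with Dykstra's correction; with ``corr=True`` the
    unit-diagonal constraint is enforced each iteration. A final eigenvalue
    step guarantees min eigenvalue >= eig_tol * max eigenvalue.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("near_pd needs a square matrix")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("near_pd needs a symmetric matrix")
    Y = (A + A.T) / 2.0
    DS = np.zeros_like(Y)
    for _ in range(max_iter):
        R = Y - DS
        w, V = eigh((R + R.T) / 2.0)
        X = (V * np.clip(w, 0.0, None)) @ V.T
        DS = X - R
        Y_new = X.copy()
        if corr:
            np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, "fro") <= conv_tol * max(np.linalg.norm(Y, "fro"), 1.0):
            Y = Y_new
            break
        Y = Y_new
    w, V = eigh((Y + Y.T) / 2.0)
    floor = eig_tol * max(w[-1], eig_tol)
    if w[0] < floor:
        w = np.maximum(w, floor)
        Y = (V * w) @ V.T
        if corr:
            d = np.sqrt(np.diag(Y))
            Y = Y / np.outer(d, d)
            np.fill_diagonal(Y, 1.0)
    return (Y + Y.T) / 2.0


# ---------------------------------------------------------------------------
# assembly


def environment_pairs(env_ids) -> list[tuple[str, str]]:
    """All unordered environment pairs, in deterministic order."""
    return list(itertools.combinations(list(env_ids), 2))


def assemble_correlation(pairwise: dict[tuple[str, str], PairwiseCovariance],
                         env_ids, eig_tol: float = 1e-8,
                         max_flagged_fraction: float = 0.2) -> pd.DataFrame:
    """Genetic correlation matrix from the pairwise covariance estimates.

    Diagonal variances average the M-1 per-pair estimates; the covariance
    matrix is repaired to PD (Higham) and standardised to unit diagonal.
    Non-converged pairs are excluded (their covariance entry falls back to
    0); more than ``max_flagged_fraction`` flagged pairs is an error.
    """
    env_ids = list(env_ids)
    M = len(env_ids)
    pos = {e: i for i, e in enumerate(env_ids)}
    n_pairs = M * (M - 1) // 2
    flagged = 0
    C = np.zeros((M, M))
    diag_sums = np.zeros(M)
    diag_counts = np.zeros(M)
    for (j, k), pc in pairwise.items():
        a, b = pos[j], pos[k]
        if not pc.converged:
            flagged += 1
            continue
        C[a, b] = C[b, a] = pc.sigma_u[0, 1]
        diag_sums[a] += pc.sigma_u[0, 0]
        diag_counts[a] += 1
        diag_sums[b] += pc.sigma_u[1, 1]
        diag_counts[b] += 1
    if flagged > max_flagged_fraction * n_pairs:
        raise RuntimeError(
            f"correlation matrix unreliable: {flagged}/{n_pairs} pairs failed to converge")
    if (diag_counts == 0).any():
        missing = [env_ids[i] for i in np.nonzero(diag_counts == 0)[0]]
        raise RuntimeError(f"no variance estimate for environments {missing}")
    np.fill_diagonal(C, np.maximum(diag_sums / diag_counts, _VAR_FLOOR))
    C = near_pd(C, eig_tol=eig_tol)
    d = np.sqrt(np.clip(np.diag(C), _VAR_FLOOR, None))
    P = C / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    P = (P + P.T) / 2.0
    w = np.linalg.eigvalsh(P)
    if w[0] < eig_tol:
        P = near_pd(P, eig_tol=eig_tol, corr=True)
    return pd.DataFrame(P, index=env_ids, columns=env_ids)
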