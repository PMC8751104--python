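"""mixed_models: REML fits, record matching, near-PD repair, assembly.

Oracles: closed-form REML of the balanced one-way classification for the
single-trait fit; a dense multivariate-normal likelihood for the bivariate
engine; frozen values from R's Matrix::nearPD for the Higham projection.
"""

import numpy as np
import pandas as pd
import pytest

from ecgc.mixed_models import (PairwiseCovariance, _BivariateREML,
                               assemble_correlation, environment_pairs,
                               fit_bivariate, fit_gblup, match_records,
                               near_pd)


def _identity_grm(q):
    ids = [f"v{i}" for i in range(q)]
    return pd.DataFrame(np.eye(q), index=ids, columns=ids), ids


def _random_grm(q, rng, k=4):
    Z = rng.normal(size=(q, k * q))
    G = Z @ Z.T / (k * q)
    ids = [f"v{i}" for i in range(q)]
    return pd.DataFrame(G, index=ids, columns=ids), ids


class TestFitGblup:
    def test_matches_balanced_anova_reml(self, rng):
        """With G = I and a balanced one-way layout, REML is closed-form:
        sigma_e^2 = MSE and sigma_u^2 = (MSB - MSE) / r."""
        q, r = 40, 4
        grm, ids = _identity_grm(q)
        u = rng.normal(0, 1.2, size=q)
        y = np.repeat(u, r) + rng.normal(0, 0.8, size=q * r) + 5.0
        labels = np.repeat(ids, r)
        X = np.ones((q * r, 1))
        fit = fit_gblup(y, X, list(labels), grm)

        Y = y.reshape(q, r)
        group_means = Y.mean(axis=1)
        mse = float(np.sum((Y - group_means[:, None]) ** 2)) / (q * (r - 1))
        msb = r * float(np.sum((group_means - y.mean()) ** 2)) / (q - 1)
        assert fit.sigma_e2 == pytest.approx(mse, rel=1e-4)
        assert fit.sigma_u2 == pytest.approx((msb - mse) / r, rel=1e-4)

    def test_blup_shrinks_group_means(self, rng):
        """With G = I the BLUPs are the shrunken adjusted group means:
        u_hat = (sigma_u^2 * r / (sigma_u^2 * r + sigma_e^2)) * (ybar_v - mu)."""
        q, r = 30, 3
        grm, ids = _identity_grm(q)
        u = rng.normal(0, 1.0, size=q)
        y = np.repeat(u, r) + rng.normal(0, 1.0, size=q * r)
        fit = fit_gblup(y, np.ones((q * r, 1)), list(np.repeat(ids, r)), grm)
        shrink = fit.sigma_u2 * r / (fit.sigma_u2 * r + fit.sigma_e2)
        expected = shrink * (y.reshape(q, r).mean(axis=1) - fit.beta[0])
        np.testing.assert_allclose(fit.u_hat.loc[ids].to_numpy(), expected,
                                   rtol=1e-4, atol=1e-8)

    def test_predicts_unobserved_varieties_through_kinship(self, rng):
        q = 60
        # strongly-related kinship (low rank + noise) so held-out varieties
        # are predictable through their relatives
        Z = rng.normal(size=(q, 5))
        G = (Z @ Z.T + np.eye(q)) / 6.0
        ids = [f"v{i}" for i in range(q)]
        grm = pd.DataFrame(G, index=ids, columns=ids)
        L = np.linalg.cholesky(grm.to_numpy() + 1e-8 * np.eye(q))
        u = L @ rng.normal(size=q)
        obs = ids[:50]  # last 10 varieties never phenotyped
        y = u[:50] + rng.normal(0, 0.5, size=50)
        fit = fit_gblup(y, np.ones((50, 1)), obs, grm)
        assert set(fit.u_hat.index) == set(ids)
        held = fit.u_hat.loc[ids[50:]].to_numpy()
        assert np.corrcoef(held, u[50:])[0, 1] > 0.3

    def test_y_adj_removes_fixed_effects(self, rng):
        q, r = 20, 2
        grm, ids = _identity_grm(q)
        y = rng.normal(size=q * r) + 7.0
        X = np.ones((q * r, 1))
        fit = fit_gblup(y, X, list(np.repeat(ids, r)), grm)
        np.testing.assert_allclose(fit.y_adj, y - X @ fit.beta, atol=1e-10)

    def test_aliased_fixed_effects_handled(self, rng):
        q, r = 20, 2
        grm, ids = _identity_grm(q)
        y = rng.normal(size=q * r)
        ones = np.ones((q * r, 1))
        X = np.hstack([ones, 2 * ones])  # perfectly collinear
        fit = fit_gblup(y, X, list(np.repeat(ids, r)), grm)
        assert np.isfinite(fit.sigma_u2) and np.isfinite(fit.sigma_e2)

    def test_single_variety_rejected(self):
        grm, ids = _identity_grm(3)
        with pytest.raises(ValueError, match=">= 2 varieties"):
            fit_gblup(np.array([1.0, 2.0]), np.ones((2, 1)),
                      [ids[0], ids[0]], grm)

    def test_h2_definition(self):
        fit_args = dict(beta=np.zeros(1), u_hat=pd.Series(dtype=float),
                        y_adj=np.zeros(1))
        from ecgc.mixed_models import GBLUPFit
        assert GBLUPFit(sigma_u2=1.0, sigma_e2=1.0, **fit_args).h2 == pytest.approx(0.5)
        assert GBLUPFit(sigma_u2=3.0, sigma_e2=1.0, **fit_args).h2 == pytest.approx(0.75)


class TestMatchRecords:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["variety_id", "year", "value"])

    def test_unique_keys_pair_directly(self, rng):
        a = self._df([("v1", 2001, 1.0), ("v2", 2001, 2.0)])
        b = self._df([("v2", 2001, 20.0), ("v1", 2001, 10.0)])
        out = match_records(a, b, rng)
        assert len(out) == 2
        row = out[out["variety_id"] == "v1"].iloc[0]
        assert (row["y_j"], row["y_k"]) == (1.0, 10.0)

    def test_leftovers_become_singles(self, rng):
        a = self._df([("v1", 2001, 1.0), ("v1", 2002, 2.0)])
        b = self._df([("v1", 2001, 10.0)])
        out = match_records(a, b, rng)
        assert len(out) == 2
        single = out[out["year"] == 2002].iloc[0]
        assert single["y_j"] == 2.0 and np.isnan(single["y_k"])

    def test_duplicate_keys_pair_all_values(self, rng):
        a = self._df([("v1", 2001, 1.0), ("v1", 2001, 2.0)])
        b = self._df([("v1", 2001, 10.0), ("v1", 2001, 20.0)])
        out = match_records(a, b, rng)
        assert len(out) == 2
        assert sorted(out["y_j"]) == [1.0, 2.0]
        assert sorted(out["y_k"]) == [10.0, 20.0]

    def test_reproducible_given_rng(self):
        a = self._df([("v1", 2001, v) for v in (1.0, 2.0, 3.0)])
        b = self._df([("v1", 2001, v) for v in (10.0, 20.0, 30.0)])
        out1 = match_records(a, b, np.random.default_rng(5))
        out2 = match_records(a, b, np.random.default_rng(5))
        pd.testing.assert_frame_equal(out1, out2)


def brute_force_neg2ll(paired, grm, su, se, jitter=1e-6):
    """Dense MVN -2 log-likelihood, assembled observation by observation."""
    vars_ = pd.Index(pd.unique(paired["variety_id"]))
    vpos = {v: i for i, v in enumerate(vars_)}
    obs = []
    for rid, r in enumerate(paired.itertuples(index=False)):
        for t, val in ((0, r.y_j), (1, r.y_k)):
            if not np.isnan(val):
                obs.append((t, vpos[r.variety_id], val, rid))
    n = len(obs)
    Gj = grm.loc[vars_, vars_].to_numpy() + jitter * np.eye(len(vars_))
    V = np.zeros((n, n))
    y = np.zeros(n)
    for a, (ta, va, ya, ra) in enumerate(obs):
        y[a] = ya
        for b, (tb, vb, _, rb) in enumerate(obs):
            V[a, b] = su[ta, tb] * Gj[va, vb] + (se[ta, tb] if ra == rb else 0.0)
    _, ld = np.linalg.slogdet(V)
    return n * np.log(2 * np.pi) + ld + float(y @ np.linalg.solve(V, y))


class TestBivariateREML:
    def _paired(self, rng, q=10):
        grm, ids = _random_grm(q, rng)
        rows = []
        for i in range(q):
            for t in range(int(rng.integers(1, 3))):
                rows.append((ids[i], 2000 + t, rng.normal(), rng.normal()))
        rows.append((ids[0], 2005, rng.normal(), np.nan))   # singles
        rows.append((ids[3], 2006, np.nan, rng.normal()))
        rows.append((ids[3], 2007, np.nan, rng.normal()))
        paired = pd.DataFrame(rows, columns=["variety_id", "year", "y_j", "y_k"])
        return paired, grm

    def test_likelihood_matches_dense_oracle(self, rng):
        paired, grm = self._paired(rng)
        eng = _BivariateREML(paired, grm)
        for _ in range(5):
            A = rng.normal(size=(2, 2)) * 0.5
            su = A @ A.T + 0.3 * np.eye(2)
            B = rng.normal(size=(2, 2)) * 0.5
            se = B @ B.T + 0.3 * np.eye(2)
            fast = eng.neg2ll(su, se)
            slow = brute_force_neg2ll(paired, grm, su, se)
            assert fast == pytest.approx(slow, rel=1e-9)

    def test_fit_is_local_minimum_of_oracle(self, rng):
        paired, grm = self._paired(rng)
        pc = fit_bivariate(paired, grm)
        base = brute_force_neg2ll(paired, grm, pc.sigma_u, pc.sigma_e)
        perturb = np.random.default_rng(0)
        for _ in range(10):
            su = pc.sigma_u + 0.05 * _sym(perturb)
            se = pc.sigma_e + 0.05 * _sym(perturb)
            if min(np.linalg.eigvalsh(su)[0], np.linalg.eigvalsh(se)[0]) <= 1e-6:
                continue
            assert brute_force_neg2ll(paired, grm, su, se) >= base - 1e-6

    def test_recovers_genetic_correlation(self, rng):
        q, rg_true = 150, 0.7
        grm, ids = _random_grm(q, rng)
        L = np.linalg.cholesky(grm.to_numpy() + 1e-8 * np.eye(q))
        Lu = np.linalg.cholesky(np.array([[1, rg_true], [rg_true, 1]]))
        ests = []
        for _ in range(3):
            U = L @ rng.normal(size=(q, 2)) @ Lu.T
            rows = []
            for t in range(2):
                Y = U + rng.normal(size=(q, 2))
                rows += [(ids[i], 2000 + t, Y[i, 0], Y[i, 1]) for i in range(q)]
            paired = pd.DataFrame(rows, columns=["variety_id", "year", "y_j", "y_k"])
            pc = fit_bivariate(paired, grm, init=(1, 1, 1, 1))
            ests.append(pc.r_g)
        assert np.mean(ests) == pytest.approx(rg_true, abs=0.2)

    def test_no_complete_rows_fixes_residual_covariance(self, rng):
        grm, ids = _random_grm(8, rng)
        rows = ([(ids[i], 2001, rng.normal(), np.nan) for i in range(4)]
                + [(ids[i], 2001, np.nan, rng.normal()) for i in range(4, 8)])
        paired = pd.DataFrame(rows, columns=["variety_id", "year", "y_j", "y_k"])
        pc = fit_bivariate(paired, grm)
        assert pc.n_complete == 0
        assert pc.sigma_e[0, 1] == 0.0

    def test_r_g_property(self):
        pc = PairwiseCovariance("a", "b", np.array([[4.0, 1.0], [1.0, 1.0]]),
                                np.eye(2))
        assert pc.r_g == pytest.approx(0.5)


def _sym(rng):
    A = rng.normal(size=(2, 2))
    return (A + A.T) / 2


class TestNearPd:
    # Frozen oracle values from R Matrix::nearPD (conv.tol 1e-10, maxit 500)
    R_CASE1_IN = np.array([[1.0, 0.9, -0.6],
                           [0.9, 1.0, 0.9],
                           [-0.6, 0.9, 1.0]])
    R_CASE1_OUT = np.array([
        [1.000000000000, 0.580837207353, -0.325256249060],
        [0.580837207353, 1.000000000000, 0.580837207353],
        [-0.325256249060, 0.580837207353, 1.000000000000]])
    R_CASE2_IN = np.array([[2.0, 1.5, -1.8, 0.3],
                           [1.5, 1.0, 0.6, 0.2],
                           [-1.8, 0.6, 3.0, -0.5],
                           [0.3, 0.2, -0.5, 0.5]])
    R_CASE2_OUT = np.array([
        [2.293616116357, 1.180456957327, -1.602100536269, 0.358132013327],
        [1.180456957327, 1.347759303072, 0.384625620007, 0.136734809947],
        [-1.602100536269, 0.384625620007, 3.133385696308, -0.460818589092],
        [0.358132013327, 0.136734809947, -0.460818589092, 0.511509350395]])

    def test_matches_r_nearpd_correlation_case(self):
        out = near_pd(self.R_CASE1_IN, corr=True)
        np.testing.assert_allclose(out, self.R_CASE1_OUT, atol=2e-7)

    def test_matches_r_nearpd_general_case(self):
        out = near_pd(self.R_CASE2_IN, corr=False)
        np.testing.assert_allclose(out, self.R_CASE2_OUT, atol=2e-7)

    def test_pd_input_unchanged(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(near_pd(A), A, atol=1e-7)

    def test_output_positive_definite(self, rng):
        for _ in range(5):
            A = rng.normal(size=(6, 6))
            A = (A + A.T) / 2
            out = near_pd(A)
            assert np.linalg.eigvalsh(out).min() > 0

    def test_corr_mode_keeps_unit_diagonal(self, rng):
        A = rng.normal(size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        out = near_pd(A, corr=True)
        np.testing.assert_allclose(np.diag(out), 1.0, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            near_pd(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestAssembly:
    def test_environment_pairs(self):
        assert environment_pairs(["a", "b", "c"]) == [("a", "b"), ("a", "c"),
                                                      ("b", "c")]
        assert len(environment_pairs(range(52))) == 1326

    def _pc(self, j, k, cov, vj=1.0, vk=1.0, converged=True):
        return PairwiseCovariance(j, k, np.array([[vj, cov], [cov, vk]]),
                                  np.eye(2), converged=converged)

    def test_consistent_input_reproduced(self):
        envs = ["A", "B", "C"]
        true = np.array([[1.0, 0.5, 0.2],
                         [0.5, 1.0, 0.4],
                         [0.2, 0.4, 1.0]])
        pairwise = {(a, b): self._pc(a, b, true[i, j])
                    for (i, a), (j, b) in
                    [((0, "A"), (1, "B")), ((0, "A"), (2, "C")), ((1, "B"), (2, "C"))]}
        P = assemble_correlation(pairwise, envs)
        np.testing.assert_allclose(P.to_numpy(), true, atol=1e-6)

    def test_diagonal_averages_per_pair_variances(self):
        envs = ["A", "B", "C"]
        pairwise = {("A", "B"): self._pc("A", "B", 0.0, vj=2.0, vk=1.0),
                    ("A", "C"): self._pc("A", "C", 0.0, vj=4.0, vk=1.0),
                    ("B", "C"): self._pc("B", "C", 0.0, vj=1.0, vk=1.0)}
        # A's variance = mean(2, 4) = 3; correlations = cov / sqrt(var)
        pairwise[("A", "B")].sigma_u[0, 1] = pairwise[("A", "B")].sigma_u[1, 0] = 1.5
        P = assemble_correlation(pairwise, envs)
        assert P.loc["A", "B"] == pytest.approx(1.5 / np.sqrt(3.0), abs=1e-6)

    def test_output_is_valid_correlation_matrix(self, rng):
        envs = [f"E{i}" for i in range(6)]
        pairwise = {}
        for a, b in environment_pairs(envs):
            pairwise[(a, b)] = self._pc(a, b, rng.uniform(-0.9, 0.9))
        P = assemble_correlation(pairwise, envs).to_numpy()
        np.testing.assert_allclose(np.diag(P), 1.0)
        np.testing.assert_allclose(P, P.T)
        assert np.linalg.eigvalsh(P).min() > 0

    def test_too_many_flagged_pairs_rejected(self):
        envs = ["A", "B", "C"]
        pairwise = {("A", "B"): self._pc("A", "B", 0.5, converged=False),
                    ("A", "C"): self._pc("A", "C", 0.5),
                    ("B", "C"): self._pc("B", "C", 0.5)}
        with pytest.raises(RuntimeError, match="unreliable"):
            assemble_correlation(pairwise, envs)
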