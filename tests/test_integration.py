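"""Elastic net screening, SUMCOR MCCA, resampling, and back-projection."""

import numpy as np
import pytest
import scipy.linalg

from olfnet import integration as ig
from olfnet import synthetic as syn
from olfnet.exceptions import ConfigurationError, DataIntegrityError


def _make_connectomes(rng, n_subjects=6, n_regions=4):
    out = []
    for _ in range(n_subjects):
        A = rng.integers(1, 40, size=(n_regions, n_regions))
        A = np.triu(A, 1)
        A = A + A.T
        out.append(ig.Connectome(region_labels=[f"R{i}" for i in range(n_regions)],
                                 adjacency=A))
    return out


class TestVectorize:
    def test_edge_count_upper_triangle(self, rng):
        edges = ig.vectorize_connectomes(_make_connectomes(rng, n_regions=4))
        assert edges.X.shape[1] == 6  # n(n-1)/2
        assert edges.edge_index[0] == ("R0", "R1")

    def test_asymmetric_input_rejected(self):
        A = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]])
        with pytest.raises(DataIntegrityError):
            ig.Connectome(region_labels=list("abc"), adjacency=A)

    def test_label_mismatch_rejected(self, rng):
        conns = _make_connectomes(rng)
        conns[1].region_labels = ["X0", "R1", "R2", "R3"]
        with pytest.raises(DataIntegrityError):
            ig.vectorize_connectomes(conns)

    def test_columns_standardized_and_constant_dropped(self, rng):
        conns = _make_connectomes(rng, n_subjects=10)
        for c in conns:  # force one edge constant
            c.adjacency[0, 1] = c.adjacency[1, 0] = 7
        edges = ig.vectorize_connectomes(conns)
        assert ("R0", "R1") in edges.dropped_edges
        assert edges.X.shape[1] == 5
        assert np.allclose(edges.X.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(edges.X.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_backprojection_restores_edge_positions(self, rng):
        conns = _make_connectomes(rng, n_subjects=8, n_regions=5)
        edges = ig.vectorize_connectomes(conns)
        iu = np.triu_indices(5, 1)
        for k, (a, b) in enumerate(edges.edge_index):
            i, j = int(a[1:]), int(b[1:])
            assert (iu[0][k], iu[1][k]) == (i, j)
            assert np.allclose(
                edges.X[:, k],
                ig._standardize(np.log1p([c.adjacency[i, j] for c in conns])
                                .reshape(-1, 1))[:, 0])


class TestElasticNetLoss:
    def test_zero_beta_is_mean_square(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        assert ig.elastic_net_loss(np.zeros(3), X, y, lam=1.0) == pytest.approx(
            (y**2).sum() / 40)

    def test_ols_solution_minimizes_unpenalized_loss(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ [1.0, -2.0, 0.5] + 0.1 * rng.standard_normal(50)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        base = ig.elastic_net_loss(beta, X, y, lam=0.0)
        for _ in range(20):
            assert base <= ig.elastic_net_loss(
                beta + 0.1 * rng.standard_normal(3), X, y, lam=0.0) + 1e-12

    def test_penalty_limits(self):
        X = np.eye(2)
        y = np.zeros(2)
        beta = np.array([3.0, -4.0])
        pure_l1 = ig.elastic_net_loss(beta, X, y, lam=2.0, alpha=1.0)
        pure_l2 = ig.elastic_net_loss(beta, X, y, lam=2.0, alpha=0.0)
        resid = ig.elastic_net_loss(beta, X, y, lam=0.0)
        assert pure_l1 - resid == pytest.approx(2.0 * 7.0)
        assert pure_l2 - resid == pytest.approx(2.0 * 25.0 / 2)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            ig.elastic_net_loss(np.zeros(2), np.eye(2), np.zeros(2), lam=-1.0)


class TestFitElasticNet:
    def test_huge_lambda_empty_selection(self, rng):
        X = ig._standardize(rng.standard_normal((40, 6)))
        y = rng.standard_normal(40)
        res = ig.fit_elastic_net(X, y, ig.ElasticNetSpec(lambda_grid=[1e6], n_folds=5))
        assert len(res.selected) == 0

    def test_coordinate_descent_matches_grid_search(self, rng):
        """2-feature toy: sklearn's coordinate descent minimizer agrees
        with a dense brute-force search of the loss surface."""
        X = ig._standardize(rng.standard_normal((60, 2)))
        y = X @ [1.2, -0.4] + 0.3 * rng.standard_normal(60)
        lam, alpha = 0.1, 0.5
        beta_cd = ig.elastic_net_path_fit(X, y, lam=lam, alpha=alpha)
        grid = np.linspace(-2, 2, 801)  # step 0.005
        losses = np.array([[ig.elastic_net_loss([b1, b2], X, y, lam, alpha)
                            for b2 in grid] for b1 in grid])
        i, j = np.unravel_index(losses.argmin(), losses.shape)
        best = np.array([grid[i], grid[j]])
        # refine around brute-force optimum to 1e-4
        fine1 = np.linspace(best[0] - 0.005, best[0] + 0.005, 101)
        fine2 = np.linspace(best[1] - 0.005, best[1] + 0.005, 101)
        losses = np.array([[ig.elastic_net_loss([b1, b2], X, y, lam, alpha)
                            for b2 in fine2] for b1 in fine1])
        i, j = np.unravel_index(losses.argmin(), losses.shape)
        assert beta_cd == pytest.approx([fine1[i], fine2[j]], abs=1e-4)

    def test_planted_support_recovered(self, rng):
        n, p = 300, 100
        X = ig._standardize(rng.standard_normal((n, p)))
        informative = [3, 17, 42, 56, 90]
        y = X[:, informative] @ np.full(5, 0.8) + rng.standard_normal(n)
        res = ig.fit_elastic_net(X, y, ig.ElasticNetSpec(seed=1))
        assert len(set(informative) & set(res.selected)) >= 4

    def test_constant_outcome_rejected(self, rng):
        X = rng.standard_normal((40, 4))
        with pytest.raises(DataIntegrityError):
            ig.fit_elastic_net(X, np.ones(40))


def _grid_sumcor_2feat(domains, step_deg=0.5):
    """Brute-force SUMCOR over unit-vector angles for 2-feature domains."""
    n = domains[0].shape[0]
    angles = np.deg2rad(np.arange(0, 180, step_deg))  # w and -w give equal sumcor
    Z = []
    for X in domains:
        Xs = ig._standardize(X)
        V = Xs @ np.stack([np.cos(angles), np.sin(angles)])
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z.append((V - V.mean(axis=0)) / sd)
    m = len(Z)
    if m == 2:
        C = np.abs(Z[0].T @ Z[1] / (n - 1))
        return C.max()
    C01 = Z[0].T @ Z[1] / (n - 1)
    C02 = Z[0].T @ Z[2] / (n - 1)
    C12 = Z[1].T @ Z[2] / (n - 1)
    best = -np.inf
    na = len(angles)
    for i in range(na):
        # sign of each domain is free; try all 4 sign patterns of (w2, w3)
        for s1 in (1, -1):
            for s2 in (1, -1):
                f = s1 * C01[i][:, None] + s2 * C02[i][None, :] + s1 * s2 * C12
                best = max(best, f.max())
    return best


class TestMCCA:
    def test_identical_domains_attain_bound(self, rng):
        X = rng.standard_normal((50, 3))
        model = ig.fit_mcca([X, X.copy(), X.copy()])
        assert model.sumcor == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(model.pairwise_corr, 1.0, atol=1e-9)

    def test_two_sets_match_classical_cca(self, rng):
        """First canonical correlation from the generalized eigenproblem
        is an independent oracle for the two-domain case."""
        for _ in range(20):
            n = 120
            X = rng.standard_normal((n, 4))
            Y = 0.4 * X[:, :3] + rng.standard_normal((n, 3))
            model = ig.fit_mcca([X, Y], tol=1e-12)
            Xs, Ys = ig._standardize(X), ig._standardize(Y)
            Sxx = Xs.T @ Xs / (n - 1)
            Syy = Ys.T @ Ys / (n - 1)
            Sxy = Xs.T @ Ys / (n - 1)
            M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
            r1 = np.sqrt(max(np.real(scipy.linalg.eigvals(M))))
            assert model.sumcor == pytest.approx(r1, abs=1e-6)

    @pytest.mark.parametrize("n_domains", [2, 3])
    def test_matches_exhaustive_grid_search(self, rng, n_domains):
        n = 60
        z = rng.standard_normal(n)
        domains = [np.column_stack([0.6 * z + 0.8 * rng.standard_normal(n),
                                    rng.standard_normal(n)])
                   for _ in range(n_domains)]
        model = ig.fit_mcca(domains, tol=1e-12)
        brute = _grid_sumcor_2feat(domains)
        assert model.sumcor == pytest.approx(brute, abs=1e-3)
        assert model.sumcor >= brute - 1e-3

    def test_monotone_history_and_bounds(self, rng):
        domains = [rng.standard_normal((80, 5)) for _ in range(4)]
        model = ig.fit_mcca(domains)
        assert np.all(np.diff(model.history) >= -1e-10)
        m = 4
        assert -m * (m - 1) / 2 <= model.sumcor <= m * (m - 1) / 2

    def test_variates_unit_variance(self, rng):
        model = ig.fit_mcca([rng.standard_normal((50, 3)) for _ in range(3)])
        assert np.allclose(model.variates.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_sign_convention(self, rng):
        model = ig.fit_mcca([rng.standard_normal((50, 3)) for _ in range(2)])
        w0 = model.weights[0]
        assert w0[np.argmax(np.abs(w0))] > 0

    def test_determinism(self, rng):
        domains = [rng.standard_normal((60, 4)) for _ in range(3)]
        a = ig.fit_mcca(domains)
        b = ig.fit_mcca([d.copy() for d in domains])
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_maxvar_close_to_sumcor_on_single_factor(self, rng):
        z = rng.standard_normal(200)
        domains = [np.column_stack([0.7 * z + 0.7 * rng.standard_normal(200),
                                    rng.standard_normal(200)])
                   for _ in range(3)]
        a = ig.fit_mcca(domains, method="sumcor")
        b = ig.fit_mcca(domains, method="maxvar")
        assert abs(a.sumcor - b.sumcor) < 0.05

    def test_planted_weight_recovery(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(10):
            n, loading = 500, 0.6
            z = rng.standard_normal(n)
            domains, planted = [], []
            for _k in range(3):
                p = 5
                X = loading * z[:, None] + np.sqrt(1 - loading**2) * rng.standard_normal((n, p))
                domains.append(X)
                planted.append(np.ones(p) / np.sqrt(p))
            model = ig.fit_mcca(domains)
            cos = [abs(w @ u) / np.linalg.norm(w) for w, u in zip(model.weights, planted)]
            hits += all(c >= 0.9 for c in cos)
        assert hits >= 9


class TestResampling:
    def test_identical_domains_degenerate_ci(self, rng):
        X = rng.standard_normal((30, 2))
        res = ig.resample_sumcor([X, X.copy(), X.copy()], B=50, P=20, seed=0)
        assert np.allclose(res.bootstrap_draws, 3.0, atol=1e-8)
        assert res.ci95[1] - res.ci95[0] == pytest.approx(0.0, abs=1e-8)

    def test_planted_factor_small_permutation_p(self):
        rng = np.random.default_rng(7)
        n = 150
        z = rng.standard_normal(n)
        domains = [0.6 * z[:, None] + 0.8 * rng.standard_normal((n, 3))
                   for _ in range(3)]
        res = ig.resample_sumcor(domains, B=100, P=199, seed=1)
        assert res.permutation_p == pytest.approx(1 / 200)
        assert res.ci95[0] < res.sumcor_observed < res.ci95[1] + 0.2

    def test_null_observed_inside_permutation_bulk(self):
        rng = np.random.default_rng(8)
        domains = [rng.standard_normal((100, 3)) for _ in range(3)]
        res = ig.resample_sumcor(domains, B=100, P=199, seed=2)
        lo, hi = np.percentile(res.permutation_draws, [1, 99])
        assert lo <= res.sumcor_observed <= hi or res.permutation_p > 0.01


class TestBackproject:
    def _model_with_weights(self, w):
        w = np.asarray(w, float)
        return ig.MCCAModel(weights=[w], variates=np.zeros((2, 1)),
                            pairwise_corr=np.eye(1), sumcor=0.0,
                            converged=True, n_iter=1, history=np.zeros(1))

    def test_published_scale_thresholding(self):
        # weights on the scale reported for the strongest connections
        model = self._model_with_weights([0.452, -0.158, 0.03])
        edges = [("A", "B"), ("C", "D"), ("E", "F")]
        res = ig.backproject_and_threshold(model, edges, threshold=0.05)
        assert len(res.retained_edges) == 2
        assert res.retained_edges[0][:2] == ("A", "B")
        assert res.stagecounts == (3, 3, 2)

    def test_zero_threshold_retains_all_nonzero(self):
        model = self._model_with_weights([0.4, -0.2, 0.0])
        res = ig.backproject_and_threshold(model, [("A", "B")] * 3, threshold=0.0)
        assert res.stagecounts[2] == 3
        assert res.stagecounts[1] == 2  # the exact zero is not MCCA-nonzero

    def test_permutation_invariance(self, rng):
        w = rng.standard_normal(6)
        edges = [(f"R{i}", f"R{i + 1}") for i in range(6)]
        base = ig.backproject_and_threshold(self._model_with_weights(w), edges)
        perm = rng.permutation(6)
        res = ig.backproject_and_threshold(self._model_with_weights(w[perm]),
                                           [edges[k] for k in perm])
        assert sorted(base.retained_edges) == sorted(res.retained_edges)

    def test_index_mismatch_rejected(self):
        model = self._model_with_weights([0.4, 0.2])
        with pytest.raises(ConfigurationError):
            ig.backproject_and_threshold(model, [("A", "B")])


class TestTraitEncoding:
    def test_full_rank_centered_standardized(self, small_traits):
        X = ig.encode_traits(small_traits)
        assert X.shape == (len(small_traits), 6)  # 2+1+1+1+1 dummy columns
        assert np.allclose(X.mean(axis=0), 0, atol=1e-12)
        assert np.linalg.matrix_rank(X) == 6
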