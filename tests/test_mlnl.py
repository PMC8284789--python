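"""Collapsed multinomial logistic-normal model: densities, gradients,
conjugate updates, evidence, and determinism."""

import numpy as np
import pytest
from scipy import optimize, stats

from pcrbias import mlnl
from pcrbias.composition import alr_basis
from pcrbias.count_data import CountTable


def _random_design(rng, Q, N):
    rows = [np.ones(N)]
    roles = ["group_intercept"]
    labels = ["int"]
    if Q >= 2:
        rows.append(rng.integers(10, 36, N).astype(float))
        roles.append("cycle")
        labels.append("cycle")
    for k in range(Q - 2):
        rows.append(rng.integers(0, 2, N).astype(float))
        roles.append("batch")
        labels.append(f"b{k}")
    return mlnl.DesignMatrix(np.vstack(rows), tuple(roles), tuple(labels))


def _random_instance(rng, D=4, N=6, Q=3, max_count=60):
    basis = alr_basis(D)
    design = _random_design(rng, Q, N)
    prior = mlnl.default_prior(D, Q, basis)
    Y = rng.integers(0, max_count, (D, N))
    table = CountTable(Y, tuple(f"t{j}" for j in range(D)), tuple(f"s{i}" for i in range(N)))
    return table, design, prior, basis


class TestDefaultPrior:
    def test_mock_study_shapes(self):
        prior = mlnl.default_prior(10, 15, sigma2=10.0)
        np.testing.assert_array_equal(prior.gamma, 10.0 * np.eye(15))
        assert prior.upsilon == 12

    def test_alr_xi(self):
        # oracle: explicit Psi Psi' for ALR rows (1,0,-1), (0,1,-1)
        prior = mlnl.default_prior(3, 2, alr_basis(3))
        np.testing.assert_allclose(prior.xi, [[2, 1], [1, 2]])

    def test_diagonal_gamma_override(self):
        g = np.diag([4.0, 4.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        prior = mlnl.default_prior(10, 9, gamma=g)
        np.testing.assert_array_equal(prior.gamma, g)

    def test_rejects_bad_sigma2(self):
        with pytest.raises(ValueError):
            mlnl.default_prior(3, 2, sigma2=-1.0)


class TestCollapse:
    def test_gamma_zero_limit(self, rng):
        design = _random_design(rng, 3, 5)
        basis = alr_basis(4)
        prior = mlnl.PriorSpec(
            theta=np.zeros((3, 3)),
            gamma=1e-12 * np.eye(3),
            xi=basis.psi @ basis.psi.T,
            upsilon=6,
        )
        coll = mlnl.collapse(prior, design)
        np.testing.assert_allclose(coll.col_scale, np.eye(5), atol=1e-7)

    def test_col_scale_positive_definite(self, rng):
        for _ in range(5):
            table, design, prior, basis = _random_instance(rng)
            coll = mlnl.collapse(prior, design)
            assert np.min(np.linalg.eigvalsh(coll.col_scale)) > 0

    def test_scalar_density_matches_quadrature(self):
        """Collapsed matrix-t equals the double integral over Lambda, Sigma."""
        from conftest import mixture_double_integral

        xi, ups, theta, gam, xq = 1.7, 4.3, 0.3, 0.8, 2.0
        A = 1 + xq * gam * xq
        for xval in (0.0, 1.3, -2.1):
            lp = mlnl.matrix_t_logpdf(
                np.array([[xval]]), np.array([[theta * xq]]),
                np.array([[xi]]), np.array([[A]]), ups,
            )
            val = mixture_double_integral(xval, xq, theta, gam, xi, ups)
            assert np.exp(lp) == pytest.approx(val, rel=1e-6)

    def test_scalar_case_is_student_t(self):
        # P=1, N=1: matrix-t reduces to Student-t(df, loc, scale^2 = xi/df)
        xi, df = 2.5, 7.0
        x = 0.9
        lp = mlnl.matrix_t_logpdf(
            np.array([[x]]), np.array([[0.2]]), np.array([[xi]]), np.array([[1.0]]), df
        )
        expected = stats.t.logpdf(x, df=df, loc=0.2, scale=np.sqrt(xi / df))
        assert lp == pytest.approx(expected, rel=1e-12)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, rng):
        table, design, prior, basis = _random_instance(rng)
        coll = mlnl.collapse(prior, design)
        post = mlnl._CollapsedPosterior(table.counts.astype(float), coll, basis)
        eta0 = rng.standard_normal(3 * 6)
        _, g = post.value_grad(eta0)
        gfd = optimize.approx_fprime(eta0, lambda e: post.value_grad(e)[0], 1e-6)
        np.testing.assert_allclose(g, gfd, rtol=1e-4, atol=1e-5)

    def test_hessian_matches_finite_differences(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=4)
        coll = mlnl.collapse(prior, design)
        post = mlnl._CollapsedPosterior(table.counts.astype(float), coll, basis)
        eta0 = 0.5 * rng.standard_normal(2 * 4)
        H = post.hessian(eta0)
        eps = 1e-5
        for k in range(eta0.size):
            e = np.zeros_like(eta0)
            e[k] = eps
            col = (post.value_grad(eta0 + e)[1] - post.value_grad(eta0 - e)[1]) / (2 * eps)
            np.testing.assert_allclose(H[:, k], col, atol=1e-6 * max(1, np.abs(H).max()))

    def test_zero_count_column_contributes_prior_only(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=4)
        Y = table.counts.copy()
        Y[:, 0] = 0
        table0 = CountTable(Y, table.taxa, table.samples)
        coll = mlnl.collapse(prior, design)
        eta = rng.standard_normal((2, 4))
        val1 = mlnl.log_posterior(eta, table0, coll, basis, return_grad=False)
        # perturbing eta of the zero sample changes only the prior term
        prior_only = mlnl.matrix_t_logpdf(eta, coll.mean, coll.row_scale, coll.col_scale, coll.df)
        Y_rest = Y[:, 1:]
        assert np.isfinite(val1)
        # multinomial part of column 0 is exactly zero
        post = mlnl._CollapsedPosterior(Y.astype(float), coll, basis)
        lik = val1 - prior_only
        post_rest = mlnl._CollapsedPosterior(
            np.hstack([np.zeros((3, 1)), Y_rest]).astype(float), coll, basis
        )
        assert lik == pytest.approx(post_rest.value_grad(eta.ravel())[0]
                                    - prior_only, rel=1e-12)

    def test_closure_invariance_of_likelihood(self, rng):
        # adding a constant to all log-parts of one sample leaves the
        # multinomial term unchanged; only possible to probe through the
        # D-space representation, so check pi is invariant
        basis = alr_basis(4)
        table, design, prior, _ = _random_instance(rng, D=4, N=3)
        coll = mlnl.collapse(prior, design)
        post = mlnl._CollapsedPosterior(table.counts.astype(float), coll, basis)
        eta = rng.standard_normal((3, 3))
        lp1 = post._log_pi(eta)
        # the same composition reached through u + c*1 (closure invariance)
        u = basis.psi_rinv @ eta + 7.3
        pi = np.exp(u) / np.exp(u).sum(axis=0, keepdims=True)
        np.testing.assert_allclose(np.exp(lp1), pi, atol=1e-12)

    def test_nonfinite_eta_rejected(self, rng):
        table, design, prior, basis = _random_instance(rng)
        coll = mlnl.collapse(prior, design)
        with pytest.raises(ValueError):
            mlnl.log_posterior(np.full((3, 6), np.nan), table, coll, basis)


class TestUncollapse:
    def test_gamma_zero_limit_pins_lambda_to_theta(self, rng):
        N, P, Q = 8, 2, 2
        design = _random_design(rng, Q, N)
        theta = rng.standard_normal((P, Q))
        prior = mlnl.PriorSpec(
            theta=theta, gamma=1e-14 * np.eye(Q),
            xi=np.eye(P), upsilon=5,
        )
        eta = rng.standard_normal((3, P, N))
        lam, _ = mlnl.uncollapse(eta, design, prior, rng=1)
        np.testing.assert_allclose(lam, np.broadcast_to(theta, lam.shape), atol=1e-5)

    def test_noise_free_recovers_ols(self, rng):
        # large N, eta exactly Lambda0 X: posterior mean -> row-wise OLS -> Lambda0
        N, P, Q = 400, 3, 2
        design = _random_design(rng, Q, N)
        lam0 = rng.standard_normal((P, Q)) * 0.3
        eta = lam0 @ design.x
        prior = mlnl.default_prior(P + 1, Q, alr_basis(P + 1), sigma2=100.0)
        lam, _ = mlnl.uncollapse(eta[None].repeat(200, axis=0), design, prior, rng=2)
        ols = eta @ np.linalg.pinv(design.x)
        np.testing.assert_allclose(lam.mean(axis=0), ols, atol=0.02)
        np.testing.assert_allclose(ols, lam0, atol=1e-8)

    def test_sigma_moments_match_conjugate_update(self, rng):
        # fixed eta: E[Sigma | eta] = Xi_N / (ups_N - P - 1), within 3 MC SEs
        N, P, Q = 6, 2, 2
        design = _random_design(rng, Q, N)
        prior = mlnl.default_prior(P + 1, Q, alr_basis(P + 1))
        eta = rng.standard_normal((P, N))
        S = 10_000
        _, sig = mlnl.uncollapse(np.repeat(eta[None], S, axis=0), design, prior, rng=3)
        X = design.x
        R = eta - prior.theta @ X
        col_inv = np.linalg.inv(np.eye(N) + X.T @ prior.gamma @ X)
        xi_N = prior.xi + R @ col_inv @ R.T
        ups_N = prior.upsilon + N
        expected = xi_N / (ups_N - P - 1)
        se = sig.std(axis=0, ddof=1) / np.sqrt(S)
        assert np.all(np.abs(sig.mean(axis=0) - expected) < 3 * se + 1e-12)


class TestFit:
    def test_symmetric_input_gives_uniform_posterior(self):
        D, N = 4, 6
        Y = np.full((D, N), 50)
        table = CountTable(Y, tuple(f"t{j}" for j in range(D)), tuple(f"s{i}" for i in range(N)))
        design = mlnl.DesignMatrix(np.ones((1, N)), ("group_intercept",), ("int",))
        f = mlnl.fit(table, design, n_draws=2000, seed=0)
        from pcrbias.composition import logratio_to_proportions

        pi = logratio_to_proportions(f.eta_draws.transpose(0, 2, 1), f.basis)
        mean_pi = pi.mean(axis=(0, 1))
        np.testing.assert_allclose(mean_pi, 0.25, atol=0.01)

    def test_deterministic_given_seed(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=5)
        f1 = mlnl.fit(table, design, prior, basis, n_draws=50, seed=42)
        f2 = mlnl.fit(table, design, prior, basis, n_draws=50, seed=42)
        assert f1.eta_draws.tobytes() == f2.eta_draws.tobytes()
        assert f1.lambda_draws.tobytes() == f2.lambda_draws.tobytes()
        assert f1.sigma_draws.tobytes() == f2.sigma_draws.tobytes()

    def test_handles_half_zero_cells_without_pseudocounts(self, rng):
        D, N = 6, 12
        Y = rng.integers(0, 8, (D, N))
        Y[rng.random((D, N)) < 0.45] = 0
        Y[0] += 1  # keep every sample nonempty
        table = CountTable(Y, tuple(f"t{j}" for j in range(D)), tuple(f"s{i}" for i in range(N)))
        assert (table.counts == 0).mean() >= 0.3
        design = _random_design(rng, 2, N)
        f = mlnl.fit(table, design, n_draws=100, seed=1)
        assert np.all(np.isfinite(f.eta_draws))
        assert np.all(np.isfinite(f.lambda_draws))

    def test_basis_equivariance_in_clr(self, rng):
        from pcrbias.composition import alr_to_clr

        table, design, prior, _ = _random_instance(rng, D=4, N=10, Q=2, max_count=200)
        out = {}
        for ref in (-1, 0):
            basis = alr_basis(4, ref)
            prior_b = mlnl.default_prior(4, design.Q, basis)
            f = mlnl.fit(table, design, prior_b, basis, n_draws=4000, seed=9)
            lam_mean = mlnl.posterior_mean_lambda(f.eta_draws, design, prior_b)
            out[ref] = alr_to_clr(lam_mean.T, basis)
        np.testing.assert_allclose(out[-1], out[0], atol=0.02)

    def test_serialization_round_trip(self, tmp_path, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=5)
        f = mlnl.fit(table, design, prior, basis, n_draws=20, seed=3)
        f.save(tmp_path / "fit.npz")
        back = mlnl.load_fit(tmp_path / "fit.npz")
        np.testing.assert_array_equal(back.eta_draws, f.eta_draws)
        np.testing.assert_array_equal(back.lambda_draws, f.lambda_draws)
        assert back.seed == f.seed
        np.testing.assert_array_equal(back.design.x, design.x)

    def test_coverage_of_generative_lambda(self):
        """95% CIs on Lambda cover the generative truth near nominally."""
        from pcrbias.simulate import simulate_from_generative

        D, N, Q = 5, 40, 2
        basis = alr_basis(D)
        cycles = np.tile(np.arange(10, 36, 5), 8)[:N].astype(float)
        design = mlnl.DesignMatrix(
            np.vstack([np.ones(N), cycles]), ("group_intercept", "cycle"), ("int", "cycle")
        )
        gamma = np.diag([1.0, 0.0025])
        prior = mlnl.PriorSpec(
            theta=np.zeros((D - 1, Q)), gamma=gamma,
            xi=basis.psi @ basis.psi.T, upsilon=D + 2,
        )
        covered = total = 0
        for seed in range(15):
            table, truth = simulate_from_generative(prior, design, depth=20_000,
                                                    basis=basis, seed=seed)
            f = mlnl.fit(table, design, prior, basis, n_draws=600, seed=seed + 500)
            lo, hi = np.quantile(f.lambda_draws, [0.025, 0.975], axis=0)
            covered += np.sum((truth["lambda"] >= lo) & (truth["lambda"] <= hi))
            total += truth["lambda"].size
        assert 0.88 <= covered / total <= 1.0


class TestEvidence:
    def test_taxon_relabeling_invariance(self, rng):
        D, N = 4, 6
        Y = rng.integers(0, 40, (D, N))
        design = _random_design(rng, 2, N)
        perm = rng.permutation(D)
        basis = alr_basis(D)
        prior = mlnl.default_prior(D, 2, basis)
        t1 = CountTable(Y, tuple(f"t{j}" for j in range(D)), tuple(f"s{i}" for i in range(N)))
        t2 = CountTable(Y[perm], tuple(f"t{j}" for j in perm), tuple(f"s{i}" for i in range(N)))
        l1 = mlnl.log_marginal_likelihood(t1, design, prior, basis)
        l2 = mlnl.log_marginal_likelihood(t2, design, prior, basis)
        assert l1 == pytest.approx(l2, abs=0.02)

    def test_matches_importance_sampling(self, rng):
        """Laplace evidence vs importance sampling from the Laplace proposal."""
        # deep counts keep the collapsed posterior in the Gaussian regime,
        # where the Laplace evidence carries only a small O(1/n) error
        D, N = 3, 8
        table, design, prior, basis = _random_instance(rng, D=D, N=N, Q=2, max_count=1000)
        lml = mlnl.log_marginal_likelihood(table, design, prior, basis)
        coll = mlnl.collapse(prior, design)
        post = mlnl._CollapsedPosterior(table.counts.astype(float), coll, basis)
        map_eta = mlnl._find_map(post, mlnl._init_eta(table.counts, basis))
        L = mlnl._laplace_factor(post, map_eta)
        dim = (D - 1) * N
        S = 4000
        g = np.random.default_rng(11)
        z = g.standard_normal((dim, S))
        from scipy import linalg as sla

        dev = sla.solve_triangular(L.T, z, lower=False)
        xs = map_eta.ravel()[:, None] + dev
        logq = (
            -0.5 * (z**2).sum(axis=0)
            - 0.5 * dim * np.log(2 * np.pi)
            + np.sum(np.log(np.diag(L)))
        )
        logp = post.value_grad_batch(xs.T)
        lw = logp - logq
        lw_max = lw.max()
        w = np.exp(lw - lw_max)
        est = lw_max + np.log(w.mean())
        mc_se = w.std(ddof=1) / (w.mean() * np.sqrt(S))
        assert abs(lml - est) < 3 * mc_se + 0.05

    def test_occam_penalty_for_overscaled_prior(self, rng):
        # Lambda = 0 data: evidence decreases monotonically in sigma2
        D, N = 3, 12
        basis = alr_basis(D)
        design = _random_design(rng, 2, N)
        g = np.random.default_rng(5)
        eta = 0.3 * g.standard_normal((D - 1, N))
        from pcrbias.composition import logratio_to_proportions

        pi = logratio_to_proportions(eta.T, basis)
        Y = np.array([g.multinomial(500, pi[i]) for i in range(N)]).T
        table = CountTable(Y, tuple(f"t{j}" for j in range(D)), tuple(f"s{i}" for i in range(N)))
        grid = np.array([1.0, 10.0, 100.0, 1000.0])
        _, profile = mlnl.select_scale(table, design, grid, basis)
        assert np.all(np.diff(profile) < 0)


class TestSelectScale:
    def test_single_value_grid(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=5)
        s2, profile = mlnl.select_scale(table, design, np.array([3.3]), basis)
        assert s2 == 3.3
        assert profile.shape == (1,)

    def test_profile_length_matches_grid(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=5)
        grid = np.array([1.0, 10.0, 100.0])
        _, profile = mlnl.select_scale(table, design, grid, basis)
        assert profile.shape == grid.shape

    def test_empty_grid_rejected(self, rng):
        table, design, prior, basis = _random_instance(rng, D=3, N=5)
        with pytest.raises(ValueError):
            mlnl.select_scale(table, design, np.array([]), basis)
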