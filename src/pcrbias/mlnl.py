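"""Bayesian multinomial logistic-normal linear regression.

The model for a taxa-by-samples count table Y with design matrix X (Q x N):

    Y_i     ~ Multinomial(pi_i)
    pi_i    = inverse log-ratio transform of eta_i
    eta_i   ~ N(Lambda X_i, Sigma)          (log-ratio coordinates, length D-1)
    Lambda  ~ MatrixNormal(Theta, Sigma, Gamma)
    Sigma   ~ InverseWishart(Xi, upsilon)

Integrating Lambda and Sigma out analytically leaves eta with a matrix-t
prior T(upsilon, Theta X, Xi, I_N + X' Gamma X). Inference finds the MAP of
eta in this collapsed space by quasi-Newton optimization with analytic
gradients, approximates the posterior of eta by a Laplace Gaussian at the
mode, and recovers Lambda and Sigma draws through the exact conjugate
("uncollapse") updates. An ensemble-MCMC reference sampler targeting the
same collapsed posterior is provided as an asymptotically exact cross-check
for small problems.

Conventions: P = D-1 log-ratio coordinates; eta is a P x N matrix; the
inverse-Wishart density is proportional to |Sigma|^{-(v+P+1)/2}
exp(-tr(Xi Sigma^{-1})/2) with mean Xi/(v-P-1), so the scalar (P=1, N=1)
matrix-t marginal is a Student-t with df upsilon and scale^2 = Xi/upsilon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import gammaln, multigammaln

from .composition import ContrastBasis, alr_basis
from .count_data import CountTable

__all__ = [
    "PriorSpec",
    "DesignMatrix",
    "CollapsedPrior",
    "PosteriorFit",
    "default_prior",
    "collapse",
    "matrix_t_logpdf",
    "log_posterior",
    "fit",
    "uncollapse",
    "log_marginal_likelihood",
    "select_scale",
    "fit_reference_mcmc",
    "load_fit",
]

_JITTER = 1e-8


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the matrix-normal / inverse-Wishart prior."""

    theta: np.ndarray  # (P, Q) prior mean of Lambda
    gamma: np.ndarray  # (Q, Q) covariate covariance
    xi: np.ndarray  # (P, P) inverse-Wishart scale
    upsilon: float  # inverse-Wishart degrees of freedom
    sigma2: float | None = None  # scalar used when gamma = sigma2 * I

    def __post_init__(self) -> None:
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "xi", xi)
        P, Q = theta.shape
        if gamma.shape != (Q, Q) or xi.shape != (P, P):
            raise ValueError("prior shapes inconsistent with theta")
        for name, m in (("gamma", gamma), ("xi", xi)):
            if not np.allclose(m, m.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(m)) <= 0:
                raise ValueError(f"{name} must be positive-definite")
        if self.upsilon <= P - 1:
            raise ValueError(f"upsilon must exceed P-1={P - 1} for a proper prior")

    @property
    def P(self) -> int:
        return self.theta.shape[0]

    @property
    def Q(self) -> int:
        return self.theta.shape[1]


_ROLES = {"group_intercept", "cycle", "batch"}


@dataclass(frozen=True)
class DesignMatrix:
    """Covariate matrix X (Q x N) with per-row role tags and names."""

    x: np.ndarray
    roles: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "labels", tuple(self.labels))
        Q = x.shape[0]
        if len(self.roles) != Q or len(self.labels) != Q:
            raise ValueError("roles/labels must have one entry per design row")
        bad = set(self.roles) - _ROLES
        if bad:
            raise ValueError(f"unknown design roles: {sorted(bad)}")
        if self.roles.count("cycle") > 1:
            raise ValueError("at most one cycle row allowed")
        for role, row in zip(self.roles, x):
            if role in ("group_intercept", "batch") and not np.isin(row, (0.0, 1.0)).all():
                raise ValueError(f"indicator rows must be 0/1 ({role})")

    @property
    def Q(self) -> int:
        return self.x.shape[0]

    @property
    def N(self) -> int:
        return self.x.shape[1]

    def rows_with_role(self, role: str) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == role]


@dataclass(frozen=True)
class CollapsedPrior:
    """Matrix-t law of eta after integrating out Lambda and Sigma."""

    mean: np.ndarray  # (P, N) = Theta X
    row_scale: np.ndarray  # (P, P) = Xi
    col_scale: np.ndarray  # (N, N) = I_N + X' Gamma X
    df: float

    def __post_init__(self) -> None:
        P, N = self.mean.shape
        if self.row_scale.shape != (P, P) or self.col_scale.shape != (N, N):
            raise ValueError("collapsed prior shapes inconsistent")


@dataclass
class PosteriorFit:
    """Posterior draws of eta, Lambda, Sigma plus the MAP and evidence."""

    eta_draws: np.ndarray  # (S, P, N)
    lambda_draws: np.ndarray  # (S, P, Q)
    sigma_draws: np.ndarray  # (S, P, P)
    basis: ContrastBasis
    map_eta: np.ndarray  # (P, N)
    log_marginal: float
    seed: int
    design: DesignMatrix | None = None
    prior: PriorSpec | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.eta_draws.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialize draws + metadata to a single .npz archive."""
        meta = dict(
            eta_draws=self.eta_draws,
            lambda_draws=self.lambda_draws,
            sigma_draws=self.sigma_draws,
            map_eta=self.map_eta,
            log_marginal=self.log_marginal,
            seed=self.seed,
            basis_psi=self.basis.psi,
            basis_rinv=self.basis.psi_rinv,
            basis_kind=self.basis.kind,
        )
        if self.design is not None:
            meta.update(
                design_x=self.design.x,
                design_roles=np.array(self.design.roles),
                design_labels=np.array(self.design.labels),
            )
        if self.prior is not None:
            meta.update(
                prior_theta=self.prior.theta,
                prior_gamma=self.prior.gamma,
                prior_xi=self.prior.xi,
                prior_upsilon=self.prior.upsilon,
            )
        np.savez_compressed(path, **meta)


def load_fit(path: str | Path) -> PosteriorFit:
    z = np.load(path, allow_pickle=False)
    basis = ContrastBasis(z["basis_psi"], z["basis_rinv"], str(z["basis_kind"]))
    design = prior = None
    if "design_x" in z:
        design = DesignMatrix(
            z["design_x"], tuple(z["design_roles"]), tuple(z["design_labels"])
        )
    if "prior_theta" in z:
        prior = PriorSpec(
            z["prior_theta"], z["prior_gamma"], z["prior_xi"], float(z["prior_upsilon"])
        )
    return PosteriorFit(
        eta_draws=z["eta_draws"],
        lambda_draws=z["lambda_draws"],
        sigma_draws=z["sigma_draws"],
        basis=basis,
        map_eta=z["map_eta"],
        log_marginal=float(z["log_marginal"]),
        seed=int(z["seed"]),
        design=design,
        prior=prior,
    )


# ---------------------------------------------------------------------------
# priors


def default_prior(
    D: int,
    Q: int,
    basis: ContrastBasis | None = None,
    sigma2: float = 10.0,
    gamma: np.ndarray | None = None,
) -> PriorSpec:
    """Weakly-informative default prior.

    Theta = 0; Gamma = sigma2 * I_Q (or an explicit ``gamma`` override, e.g.
    a diagonal giving intercepts a larger scale than other covariates);
    Xi = Psi I_D Psi', encoding independence of taxa on the absolute
    log-abundance scale; upsilon = D + 2.
    """
    if D < 2 or Q < 1:
        raise ValueError("need D >= 2 and Q >= 1")
    if basis is None:
        basis = alr_basis(D)
    if gamma is None:
        if sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        gamma = sigma2 * np.eye(Q)
        s2 = sigma2
    else:
        gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
        s2 = None
    xi = basis.psi @ basis.psi.T
    return PriorSpec(
        theta=np.zeros((D - 1, Q)), gamma=gamma, xi=xi, upsilon=D + 2, sigma2=s2
    )


def collapse(prior: PriorSpec, design: DesignMatrix) -> CollapsedPrior:
    """Integrate Lambda and Sigma out of the prior for eta.

    eta | Sigma ~ MN(Theta X, Sigma, I_N + X' Gamma X) after marginalizing
    Lambda, and marginalizing Sigma ~ IW(Xi, upsilon) turns that into the
    matrix-t returned here.
    """
    if prior.Q != design.Q:
        raise ValueError(f"prior has Q={prior.Q} but design has Q={design.Q}")
    X = design.x
    col_scale = np.eye(design.N) + X.T @ prior.gamma @ X
    col_scale = 0.5 * (col_scale + col_scale.T)
    try:
        linalg.cholesky(col_scale, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        cond = np.linalg.cond(col_scale)
        raise linalg.LinAlgError(
            f"collapsed column scale not positive-definite (condition number {cond:.3g})"
        ) from exc
    return CollapsedPrior(
        mean=prior.theta @ X, row_scale=prior.xi, col_scale=col_scale, df=prior.upsilon
    )


# ---------------------------------------------------------------------------
# densities


def matrix_t_logpdf(
    x: np.ndarray, mean: np.ndarray, row_scale: np.ndarray, col_scale: np.ndarray, df: float
) -> float:
    """Log density of the matrix-t distribution T(df, mean, row_scale, col_scale).

    For a P x N argument:
        log p = -NP/2 log(pi) - P/2 log|A| + df/2 log|Xi|
                + log GammaP((df+N)/2) - log GammaP(df/2)
                - (df+N)/2 log|Xi + R A^-1 R'|,   R = x - mean.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    P, N = x.shape
    R = x - mean
    A_chol = linalg.cho_factor(col_scale, lower=True)
    S = R @ linalg.cho_solve(A_chol, R.T)
    _, logdet_A = np.linalg.slogdet(col_scale)
    _, logdet_Xi = np.linalg.slogdet(row_scale)
    _, logdet_post = np.linalg.slogdet(row_scale + S)
    return float(
        -0.5 * N * P * np.log(np.pi)
        - 0.5 * P * logdet_A
        + 0.5 * df * logdet_Xi
        + multigammaln((df + N) / 2.0, P)
        - multigammaln(df / 2.0, P)
        - 0.5 * (df + N) * logdet_post
    )


class _CollapsedPosterior:
    """Value/gradient/Hessian of the collapsed log posterior over eta.

    Precomputes the Cholesky of the column scale; eta is handled as a P x N
    matrix, flattened row-major where a vector is needed.
    """

    def __init__(self, Y: np.ndarray, collapsed: CollapsedPrior, basis: ContrastBasis):
        self.Y = np.asarray(Y, dtype=float)
        self.n = self.Y.sum(axis=0)  # per-sample totals
        self.collapsed = collapsed
        self.basis = basis
        self.P, self.N = collapsed.mean.shape
        self.A_chol = linalg.cho_factor(collapsed.col_scale, lower=True)
        self.A_inv = linalg.cho_solve(self.A_chol, np.eye(self.N))
        _, logdet_A = np.linalg.slogdet(collapsed.col_scale)
        _, logdet_Xi = np.linalg.slogdet(collapsed.row_scale)
        df = collapsed.df
        self.prior_const = (
            -0.5 * self.N * self.P * np.log(np.pi)
            - 0.5 * self.P * logdet_A
            + 0.5 * df * logdet_Xi
            + multigammaln((df + self.N) / 2.0, self.P)
            - multigammaln(df / 2.0, self.P)
        )
        # multinomial normalizing constants (independent of eta)
        self.mult_const = float(
            np.sum(gammaln(self.n + 1.0)) - np.sum(gammaln(self.Y + 1.0))
        )

    # -- likelihood pieces -------------------------------------------------
    def _log_pi(self, eta: np.ndarray) -> np.ndarray:
        u = self.basis.psi_rinv @ eta  # (D, N) log-parts up to constants
        u = u - u.max(axis=0, keepdims=True)
        return u - np.log(np.exp(u).sum(axis=0, keepdims=True))

    def value_grad(self, eta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = eta.reshape(self.P, self.N)
        if not np.all(np.isfinite(eta)):
            raise ValueError("eta must be finite")
        log_pi = self._log_pi(eta)
        pi = np.exp(log_pi)
        loglik = self.mult_const + float(np.sum(self.Y * log_pi))
        grad_lik = self.basis.psi_rinv.T @ (self.Y - self.n * pi)

        R = eta - self.collapsed.mean
        RAinv = R @ self.A_inv
        S = RAinv @ R.T
        M = self.collapsed.row_scale + S
        M_chol = linalg.cho_factor(0.5 * (M + M.T), lower=True)
        _, logdet_M = np.linalg.slogdet(M)
        df = self.collapsed.df
        logprior = self.prior_const - 0.5 * (df + self.N) * logdet_M
        grad_prior = -(df + self.N) * linalg.cho_solve(M_chol, RAinv)
        return loglik + logprior, (grad_lik + grad_prior).ravel()

    def value_grad_batch(self, etas: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for a (W, P*N) batch (MCMC use)."""
        W = etas.shape[0]
        eta = etas.reshape(W, self.P, self.N)
        u = np.einsum("dp,wpn->wdn", self.basis.psi_rinv, eta)
        u = u - u.max(axis=1, keepdims=True)
        log_pi = u - np.log(np.exp(u).sum(axis=1, keepdims=True))
        loglik = self.mult_const + np.einsum("dn,wdn->w", self.Y, log_pi)
        R = eta - self.collapsed.mean
        RAinv = np.einsum("wpn,nm->wpm", R, self.A_inv)
        S = np.einsum("wpm,wqm->wpq", RAinv, R)
        M = self.collapsed.row_scale + S
        _, logdet_M = np.linalg.slogdet(M)
        df = self.collapsed.df
        return loglik + self.prior_const - 0.5 * (df + self.N) * logdet_M

    # -- Hessian -----------------------------------------------------------
    def hessian(self, eta: np.ndarray) -> np.ndarray:
        """Analytic Hessian of the log posterior, (P*N) x (P*N), row-major.

        Multinomial term: block-diagonal over samples with blocks
        -n_i B'(diag(pi_i) - pi_i pi_i')B, B = psi_rinv. Matrix-t term:
        with K = (Xi + S)^{-1}, C = K R A^{-1}, V = A^{-1} R' K R A^{-1},
        H[(p,q),(r,s)] = -(df+N) [ K[p,r](A^{-1} - V)[q,s] - C[p,s] C[r,q] ].
        """
        eta = eta.reshape(self.P, self.N)
        pi = np.exp(self._log_pi(eta))  # (D, N)
        B = self.basis.psi_rinv  # (D, P)
        PN = self.P * self.N
        H = np.zeros((PN, PN))
        idx = np.arange(self.P) * self.N
        for i in range(self.N):
            W = np.diag(pi[:, i]) - np.outer(pi[:, i], pi[:, i])
            block = -self.n[i] * (B.T @ W @ B)
            H[np.ix_(idx + i, idx + i)] += block

        R = eta - self.collapsed.mean
        RAinv = R @ self.A_inv
        S = RAinv @ R.T
        M = self.collapsed.row_scale + S
        K = linalg.cho_solve(linalg.cho_factor(0.5 * (M + M.T), lower=True), np.eye(self.P))
        C = K @ RAinv  # (P, N)
        V = RAinv.T @ K @ RAinv  # (N, N)
        df = self.collapsed.df
        Hp = np.kron(K, self.A_inv - V)
        Hp -= np.einsum("ps,rq->pqrs", C, C).reshape(PN, PN)
        H += -(df + self.N) * Hp
        return H


def log_posterior(
    eta: np.ndarray,
    counts: CountTable,
    collapsed: CollapsedPrior,
    basis: ContrastBasis,
    return_grad: bool = True,
):
    """Collapsed log posterior of eta (multinomial + matrix-t), with gradient.

    Includes the multinomial normalizing constants so that the value can be
    used directly in marginal-likelihood computations.
    """
    post = _CollapsedPosterior(counts.counts, collapsed, basis)
    val, grad = post.value_grad(np.asarray(eta, dtype=float).ravel())
    if return_grad:
        return val, grad.reshape(collapsed.mean.shape)
    return val


# ---------------------------------------------------------------------------
# inference


def _init_eta(Y: np.ndarray, basis: ContrastBasis) -> np.ndarray:
    """Starting point: log-ratios of closure(counts + 0.5), initialization only."""
    smoothed = Y + 0.5
    props = smoothed / smoothed.sum(axis=0, keepdims=True)
    return basis.psi @ np.log(props)


def _find_map(post: _CollapsedPosterior, eta0: np.ndarray, gtol: float = 1e-8) -> np.ndarray:
    """Quasi-Newton burn-in followed by Newton polish with the exact Hessian.

    Convergence when the relative gradient norm |g|_inf / max(1, |f|) drops
    below ``gtol``; L-BFGS alone stalls short of that on deep count data, so
    a few damped Newton steps finish the job quadratically.
    """

    def neg(v):
        val, grad = post.value_grad(v)
        return -val, -grad

    res = optimize.minimize(
        neg,
        eta0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 10_000, "ftol": 1e-12, "gtol": 1e-7},
    )
    x = res.x
    val, grad = post.value_grad(x)
    for _ in range(50):
        rel = np.max(np.abs(grad)) / max(1.0, abs(val))
        if rel <= gtol:
            return x.reshape(post.P, post.N)
        H = post.hessian(x)
        negH = -0.5 * (H + H.T) + _JITTER * np.eye(H.shape[0])
        try:
            step = linalg.cho_solve(linalg.cho_factor(negH, lower=True), grad)
        except linalg.LinAlgError:
            step = np.linalg.solve(negH + 1e-6 * np.eye(H.shape[0]), grad)
        gnorm = np.max(np.abs(grad))
        t = 1.0
        accepted = False
        for _ in range(40):  # backtracking line search
            cand = x + t * step
            try:
                val_c, grad_c = post.value_grad(cand)
            except (ValueError, linalg.LinAlgError):
                t /= 2
                continue
            # accept ascent, or gradient reduction (value is flat to machine
            # precision in the terminal Newton steps)
            if val_c >= val - 1e-9 * max(1.0, abs(val)) and (
                val_c >= val or np.max(np.abs(grad_c)) < gnorm
            ):
                x, val, grad = cand, val_c, grad_c
                accepted = True
                break
            t /= 2
        if not accepted:
            break
    rel = np.max(np.abs(grad)) / max(1.0, abs(val))
    if rel > 1e-6:
        raise RuntimeError(
            f"MAP optimizer did not converge: |grad|_inf={np.max(np.abs(grad)):.3g}, "
            f"relative={rel:.3g} (tolerance 1e-6)"
        )
    return x.reshape(post.P, post.N)


def _laplace_factor(post: _CollapsedPosterior, map_eta: np.ndarray):
    """Cholesky of the negative Hessian at the mode (with tiny jitter)."""
    H = post.hessian(map_eta.ravel())
    negH = -0.5 * (H + H.T) + _JITTER * np.eye(H.shape[0])
    try:
        L = linalg.cholesky(negH, lower=True)
    except linalg.LinAlgError as exc:
        raise RuntimeError(
            "Hessian at the mode is not negative-definite even after "
            "regularization; consider strengthening the prior"
        ) from exc
    return L


def uncollapse(
    eta_draws: np.ndarray,
    design: DesignMatrix,
    prior: PriorSpec,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover Lambda and Sigma draws from eta draws by conjugate updates.

    For each eta draw the regression eta = Lambda X + E with the matrix-normal
    / inverse-Wishart prior has the closed-form posterior

        Sigma | eta ~ IW(Xi_N, upsilon + N),
        Xi_N = Xi + (eta - Theta X)(I_N + X' Gamma X)^{-1}(eta - Theta X)',
        Lambda | Sigma, eta ~ MN(Theta_N, Sigma, Gamma_N),
        Gamma_N = (Gamma^{-1} + X X')^{-1},
        Theta_N = (Theta Gamma^{-1} + eta X') Gamma_N.
    """
    rng = np.random.default_rng(rng)
    eta_draws = np.asarray(eta_draws, dtype=float)
    if eta_draws.ndim == 2:
        eta_draws = eta_draws[None]
    S_draws, P, N = eta_draws.shape
    X = design.x
    gamma_inv = np.linalg.inv(prior.gamma)
    gamma_N = np.linalg.inv(gamma_inv + X @ X.T)
    gamma_N = 0.5 * (gamma_N + gamma_N.T)
    col_scale_inv = np.linalg.inv(np.eye(N) + X.T @ prior.gamma @ X)
    chol_gamma_N = linalg.cholesky(gamma_N, lower=True)
    ups_N = prior.upsilon + N

    lam = np.empty((S_draws, P, prior.Q))
    sig = np.empty((S_draws, P, P))
    mean_prior = prior.theta @ X
    for s in range(S_draws):
        eta = eta_draws[s]
        R = eta - mean_prior
        xi_N = prior.xi + R @ col_scale_inv @ R.T
        xi_N = 0.5 * (xi_N + xi_N.T)
        sigma = stats.invwishart.rvs(df=ups_N, scale=xi_N, random_state=rng)
        sigma = np.atleast_2d(sigma)
        theta_N = (prior.theta @ gamma_inv + eta @ X.T) @ gamma_N
        z = rng.standard_normal((P, prior.Q))
        chol_sigma = linalg.cholesky(sigma + _JITTER * np.eye(P), lower=True)
        lam[s] = theta_N + chol_sigma @ z @ chol_gamma_N.T
        sig[s] = sigma
    return lam, sig


def posterior_mean_lambda(
    eta_draws: np.ndarray, design: DesignMatrix, prior: PriorSpec
) -> np.ndarray:
    """Rao-Blackwellized posterior mean of Lambda.

    E[Lambda | Y] = E_eta[ E[Lambda | eta] ] and the inner expectation is the
    conjugate update Theta_N(eta) in closed form, so averaging Theta_N over
    eta draws gives the posterior mean without Sigma/Lambda sampling noise.
    Theta_N is linear in eta, so this equals Theta_N evaluated at the mean
    eta draw.
    """
    eta_bar = np.asarray(eta_draws, dtype=float).mean(axis=0)
    X = design.x
    gamma_inv = np.linalg.inv(prior.gamma)
    gamma_N = np.linalg.inv(gamma_inv + X @ X.T)
    return (prior.theta @ gamma_inv + eta_bar @ X.T) @ gamma_N


def fit(
    counts: CountTable,
    design: DesignMatrix,
    prior: PriorSpec | None = None,
    basis: ContrastBasis | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> PosteriorFit:
    """MAP + Laplace inference for the collapsed model, then uncollapse.

    Optimizes the collapsed log posterior of eta with analytic gradients,
    draws ``n_draws`` samples from the Gaussian Laplace approximation at the
    mode, and converts each into Lambda and Sigma draws through the conjugate
    updates. Deterministic given ``seed``.
    """
    if basis is None:
        basis = alr_basis(counts.D)
    if prior is None:
        prior = default_prior(counts.D, design.Q, basis)
    if design.N != counts.N:
        raise ValueError(f"design has N={design.N} but counts has N={counts.N}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    collapsed = collapse(prior, design)
    post = _CollapsedPosterior(counts.counts, collapsed, basis)
    map_eta = _find_map(post, _init_eta(counts.counts, basis))
    L = _laplace_factor(post, map_eta)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((post.P * post.N, n_draws))
    # draws ~ N(map, (-H)^{-1}): solve L' x = z for the Cholesky L of -H
    dev = linalg.solve_triangular(L.T, z, lower=False)
    eta_draws = map_eta.ravel()[None, :] + dev.T
    eta_draws = eta_draws.reshape(n_draws, post.P, post.N)

    lam, sig = uncollapse(eta_draws, design, prior, rng)
    val, _ = post.value_grad(map_eta.ravel())
    logdet_negH = 2.0 * np.sum(np.log(np.diag(L)))
    log_marginal = val + 0.5 * post.P * post.N * np.log(2 * np.pi) - 0.5 * logdet_negH
    return PosteriorFit(
        eta_draws=eta_draws,
        lambda_draws=lam,
        sigma_draws=sig,
        basis=basis,
        map_eta=map_eta,
        log_marginal=float(log_marginal),
        seed=seed,
        design=design,
        prior=prior,
    )


def log_marginal_likelihood(
    counts: CountTable,
    design: DesignMatrix,
    prior: PriorSpec,
    basis: ContrastBasis | None = None,
) -> float:
    """Laplace estimate of the model evidence p(Y | prior, design).

    Computed as the collapsed log posterior at the MAP (multinomial
    normalizing constants included) plus the Gaussian volume correction
    (PN/2) log(2 pi) - (1/2) log det(-H).
    """
    if basis is None:
        basis = alr_basis(counts.D)
    collapsed = collapse(prior, design)
    post = _CollapsedPosterior(counts.counts, collapsed, basis)
    map_eta = _find_map(post, _init_eta(counts.counts, basis))
    L = _laplace_factor(post, map_eta)
    val, _ = post.value_grad(map_eta.ravel())
    logdet_negH = 2.0 * np.sum(np.log(np.diag(L)))
    return float(val + 0.5 * post.P * post.N * np.log(2 * np.pi) - 0.5 * logdet_negH)


def select_scale(
    counts: CountTable,
    design: DesignMatrix,
    sigma2_grid: np.ndarray,
    basis: ContrastBasis | None = None,
) -> tuple[float, np.ndarray]:
    """Choose the prior scale sigma^2 by maximum marginal likelihood.

    Evaluates the Laplace evidence on a grid of sigma^2 values (each defining
    Gamma = sigma^2 I) and returns the maximizer plus the full profile. On
    ties/plateaus the smallest maximizer is returned with a warning.
    """
    grid = np.asarray(sigma2_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("sigma2 grid must be nonempty and positive")
    if basis is None:
        basis = alr_basis(counts.D)
    profile = np.array(
        [
            log_marginal_likelihood(
                counts, design, default_prior(counts.D, design.Q, basis, sigma2=s2), basis
            )
            for s2 in grid
        ]
    )
    best = np.max(profile)
    maximizers = grid[np.isclose(profile, best, rtol=0, atol=1e-9)]
    if maximizers.size > 1:
        warnings.warn("marginal-likelihood profile has ties; returning smallest maximizer",
                      stacklevel=2)
    return float(np.min(maximizers)), profile


def fit_reference_mcmc(
    counts: CountTable,
    design: DesignMatrix,
    prior: PriorSpec | None = None,
    basis: ContrastBasis | None = None,
    chains: int = 4,
    n_steps: int = 2000,
    n_burn: int = 1000,
    thin: int = 4,
    seed: int = 0,
) -> PosteriorFit:
    """Asymptotically exact reference sampler for the collapsed posterior.

    Runs ``chains`` independent affine-invariant ensemble samplers on the
    collapsed posterior of eta, pools post-burn-in draws, and attaches split
    R-hat convergence diagnostics (a warning is attached when max R-hat
    exceeds 1.05). Intended for small instances as a cross-check of the
    MAP + Laplace scheme.
    """
    import arviz as az
    import emcee

    if basis is None:
        basis = alr_basis(counts.D)
    if prior is None:
        prior = default_prior(counts.D, design.Q, basis)
    collapsed = collapse(prior, design)
    post = _CollapsedPosterior(counts.counts, collapsed, basis)
    dim = post.P * post.N
    n_walkers = max(2 * dim + 2, 16)
    if n_walkers % 2:
        n_walkers += 1
    map_eta = _find_map(post, _init_eta(counts.counts, basis))

    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(chains):
        chain_seed = int(rng.integers(2**31 - 1))
        crng = np.random.default_rng(chain_seed)
        p0 = map_eta.ravel()[None, :] + 0.05 * crng.standard_normal((n_walkers, dim))
        sampler = emcee.EnsembleSampler(
            n_walkers, dim, post.value_grad_batch, vectorize=True
        )
        # the random_state property setter silently ignores non-state inputs
        sampler._random = np.random.RandomState(chain_seed)
        sampler.run_mcmc(p0, n_steps, progress=False)
        chain = sampler.get_chain(discard=n_burn, thin=thin)  # (steps, walkers, dim)
        pooled.append(chain.reshape(-1, dim))

    # split-R-hat across the independent ensemble runs
    min_len = min(c.shape[0] for c in pooled)
    stacked = np.stack([c[:min_len] for c in pooled], axis=0)  # (chains, draws, dim)
    rhat = az.rhat(az.convert_to_dataset(stacked))["x"].values
    diagnostics = {"rhat_max": float(np.max(rhat)), "rhat": rhat}
    if diagnostics["rhat_max"] > 1.05:
        diagnostics["warning"] = (
            f"max R-hat {diagnostics['rhat_max']:.3f} > 1.05; chains may not have converged"
        )
        warnings.warn(diagnostics["warning"], stacklevel=2)

    eta_flat = np.concatenate(pooled, axis=0)
    eta_draws = eta_flat.reshape(-1, post.P, post.N)
    lam, sig = uncollapse(eta_draws, design, prior, rng)
    return PosteriorFit(
        eta_draws=eta_draws,
        lambda_draws=lam,
        sigma_draws=sig,
        basis=basis,
        map_eta=map_eta,
        log_marginal=float("nan"),
        seed=seed,
        design=design,
        prior=prior,
        diagnostics=diagnostics,
    )
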