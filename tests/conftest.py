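import numpy as np
import pytest

from pcrbias import calibration, simulate
from pcrbias.composition import closure
from pcrbias.count_data import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table(rng):
    Y = rng.integers(0, 60, size=(4, 8))
    return CountTable(Y, tuple(f"taxon_{j}" for j in range(4)),
                      tuple(f"s{i}" for i in range(8)))


@pytest.fixture(scope="session")
def mock_study():
    """One default simulated calibration + mock-community study."""
    return simulate.simulate_mock_study(seed=7)


@pytest.fixture(scope="session")
def mock_study_bias(mock_study):
    cd = calibration.build_design(mock_study.metadata, mock_study.counts.samples)
    return calibration.estimate_bias(mock_study.counts, cd, n_draws=400, seed=3)


def random_composition(rng, D):
    return closure(rng.gamma(2.0, size=D) + 1e-3)


def mixture_double_integral(xval, xq, theta, gam, xi, ups):
    """Numerical double integration of the scalar latent-coefficient model.

    Integrates N(x | lam*xq, sig) * N(lam | theta, sig*gam) * IW(sig | xi, ups)
    over (lam, sig) by nested adaptive quadrature: the inner Gaussian product
    over a window around its analytic peak, the outer inverse-Wishart mixture
    in log-sigma between extreme quantiles (the 1-D inverse-Wishart is an
    inverse-gamma). Oracle accuracy ~1e-8 relative or better.
    """
    from scipy import integrate, stats

    ig = stats.invgamma(a=ups / 2, scale=xi / 2)
    u_lo, u_hi = np.log(ig.ppf(1e-11)), np.log(ig.ppf(1 - 1e-11))

    def inner(sig):
        prec = xq * xq / sig + 1.0 / (sig * gam)
        m = (xval * xq / sig + theta / (sig * gam)) / prec
        hw = 9.0 / np.sqrt(prec)

        def f(lam):
            return stats.norm.pdf(xval, lam * xq, np.sqrt(sig)) * stats.norm.pdf(
                lam, theta, np.sqrt(sig * gam)
            )

        v, _ = integrate.quad(f, m - hw, m + hw, epsabs=1e-15, epsrel=1e-9, limit=100)
        return v

    def g(u):
        return inner(np.exp(u)) * ig.pdf(np.exp(u)) * np.exp(u)

    v, _ = integrate.quad(g, u_lo, u_hi, epsabs=1e-15, epsrel=1e-8, limit=200)
    return v
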