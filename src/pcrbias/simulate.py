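"""Synthetic calibration experiments and mock-community studies.

The generator mirrors the assumed data-generating process: each taxon j has
a pre-amplification abundance a_j and a per-cycle amplification efficiency
b_j, so after x cycles its expected abundance is a_j * b_j^x. A sequenced
sample observes a multinomial draw whose proportions are the closure of
those abundances, with logistic-normal noise on the log-ratio scale and
optional per-machine (batch) perturbations in CLR space.

Defaults emulate the calibration-experiment design the model is built for:
10 taxa, calibration aliquots at every cycle from 10 to 35, held-out mock
communities amplified for 35 cycles, 5e4 reads per sample, and efficiencies
scattered log-normally around 2 (slightly imperfect doubling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .composition import (
    Composition,
    ContrastBasis,
    alr_basis,
    closure,
    logratio_to_proportions,
)
from .count_data import CountTable, SampleMetadata, write_counts, write_metadata
from .mlnl import DesignMatrix, PriorSpec

__all__ = [
    "SimulationConfig",
    "simulate_calibration",
    "draw_constrained_composition",
    "simulate_mock_study",
    "simulate_from_generative",
    "default_efficiencies",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated calibration experiment."""

    true_a: Composition  # pre-PCR composition
    true_b: np.ndarray  # per-cycle efficiencies, one per taxon
    cycles: tuple[int, ...] = tuple(range(10, 36))
    replicates_per_cycle: int = 1
    depth: int = 50_000
    noise_sigma: float | np.ndarray = 0.0  # scalar sd or (D-1, D-1) covariance
    batch_effects: dict[str, np.ndarray] | None = None  # batch -> CLR vector
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.true_b, dtype=float)
        object.__setattr__(self, "true_b", b)
        if b.shape != (self.true_a.D,):
            raise ValueError("true_b must have one efficiency per taxon")
        if np.any(b <= 0):
            raise ValueError("efficiencies must be positive")
        if any(c < 0 for c in self.cycles) or not self.cycles:
            raise ValueError("cycles must be nonnegative and nonempty")
        if self.replicates_per_cycle < 1:
            raise ValueError("replicates_per_cycle must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def D(self) -> int:
        return self.true_a.D


def default_efficiencies(D: int, rng: np.random.Generator, sd: float = 0.05) -> np.ndarray:
    """Per-taxon efficiencies log-normal around 2 (imperfect doubling)."""
    return 2.0 * np.exp(sd * rng.standard_normal(D))


def _noise_chol(noise_sigma, P: int) -> np.ndarray | None:
    if np.isscalar(noise_sigma):
        if noise_sigma == 0:
            return None
        if noise_sigma < 0:
            raise ValueError("noise scale must be >= 0")
        return float(noise_sigma) * np.eye(P)
    cov = np.atleast_2d(np.asarray(noise_sigma, dtype=float))
    if cov.shape != (P, P):
        raise ValueError(f"noise covariance must be ({P}, {P})")
    w, V = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.any(w < -1e-10):
        raise ValueError("noise covariance must be positive-semidefinite")
    return V @ np.diag(np.sqrt(np.clip(w, 0, None)))


def _sample_counts(
    expected: Composition,
    noise_L: np.ndarray | None,
    batch_clr: np.ndarray | None,
    depth: int,
    basis: ContrastBasis,
    rng: np.random.Generator,
) -> np.ndarray:
    eta = basis.psi @ np.log(expected.parts)
    if noise_L is not None:
        eta = eta + noise_L @ rng.standard_normal(basis.D - 1)
    pi = logratio_to_proportions(eta, basis)
    if batch_clr is not None:
        pi = pi * np.exp(batch_clr)
        pi = pi / pi.sum()
    if depth == 0:
        return np.zeros(basis.D, dtype=np.int64)
    return rng.multinomial(depth, pi)


def expected_composition(config: SimulationConfig, cycle: int) -> Composition:
    """Noise-free composition after ``cycle`` cycles: closure(a * b^cycle)."""
    return closure(config.true_a.parts * config.true_b**cycle)


def simulate_calibration(
    config: SimulationConfig,
    basis: ContrastBasis | None = None,
    group: str = "calibration",
    batch_of_sample=None,
) -> tuple[CountTable, SampleMetadata, dict]:
    """Simulate one calibration curve: aliquots of a pooled sample amplified
    for varying cycle numbers, then sequenced.

    Returns the count table, metadata (cycle/group/batch per sample) and a
    ground-truth record with the generating parameters and noise-free
    expected compositions.
    """
    if basis is None:
        basis = alr_basis(config.D)
    rng = np.random.default_rng(config.seed)
    noise_L = _noise_chol(config.noise_sigma, config.D - 1)
    batches = sorted(config.batch_effects) if config.batch_effects else ["batch1"]

    counts, rows, samples = [], [], []
    k = 0
    for x in config.cycles:
        for rep in range(config.replicates_per_cycle):
            sid = f"{group}_c{x:02d}_r{rep + 1}"
            batch = (
                batch_of_sample(k) if batch_of_sample is not None else batches[k % len(batches)]
            )
            bclr = config.batch_effects.get(batch) if config.batch_effects else None
            y = _sample_counts(
                expected_composition(config, x), noise_L, bclr, config.depth, basis, rng
            )
            counts.append(y)
            samples.append(sid)
            rows.append({"sample_id": sid, "cycle": x, "group": group, "batch": batch})
            k += 1
    taxa = config.true_a.labels or tuple(f"taxon_{j + 1}" for j in range(config.D))
    table = CountTable(np.array(counts).T, taxa, tuple(samples))
    meta = SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))
    truth = {
        "true_a": config.true_a,
        "true_b": config.true_b,
        "true_beta": basis.psi @ np.log(config.true_b),
        "basis": basis,
        "expected": {x: expected_composition(config, x) for x in config.cycles},
        "config": config,
    }
    return table, meta, truth


def draw_constrained_composition(
    D: int,
    max_fold: float = 10.0,
    rng: np.random.Generator | int | None = None,
    max_attempts: int = 1_000_000,
) -> Composition:
    """Uniform draw from the simplex conditioned on max(p)/min(p) <= max_fold.

    Rejection sampling from the flat Dirichlet; exact but increasingly slow
    as D grows for a fixed fold bound. The constraint keeps random mock
    communities within the dynamic range of ordinary lab pipetting.
    """
    if max_fold <= 1:
        raise ValueError("max_fold must exceed 1")
    rng = np.random.default_rng(rng)
    for _ in range(max_attempts):
        p = rng.dirichlet(np.ones(D))
        if p.max() / p.min() <= max_fold:
            return Composition(p)
    raise RuntimeError(
        f"constrained simplex sampling failed after {max_attempts} attempts "
        f"(D={D} may be too large for max_fold={max_fold})"
    )


@dataclass(frozen=True)
class MockStudy:
    """A simulated calibration curve plus held-out mock communities."""

    counts: CountTable
    metadata: SampleMetadata
    truth: dict = field(repr=False)


def simulate_mock_study(
    D: int = 10,
    n_mock: int = 10,
    cycles: tuple[int, ...] = tuple(range(10, 36)),
    study_cycles: int = 35,
    replicates_per_cycle: int = 1,
    depth: int = 50_000,
    noise_sigma: float | np.ndarray = 0.10,
    max_fold: float = 10.0,
    batch_effects: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> MockStudy:
    """Simulate the full validation design: one calibration curve sampled at
    every cycle in ``cycles`` plus ``n_mock`` random mock communities (fold
    change between any two parts at most ``max_fold``) amplified for
    ``study_cycles`` cycles, all sharing one set of true efficiencies.
    """
    rng = np.random.default_rng(seed)
    basis = alr_basis(D)
    true_b = default_efficiencies(D, rng)
    cal_a = Composition(np.full(D, 1.0 / D))  # pooled calibration sample
    noise_L = _noise_chol(noise_sigma, D - 1)
    batches = sorted(batch_effects) if batch_effects else ["batch1"]

    cal_config = SimulationConfig(
        true_a=cal_a,
        true_b=true_b,
        cycles=tuple(cycles),
        replicates_per_cycle=replicates_per_cycle,
        depth=depth,
        noise_sigma=noise_sigma,
        batch_effects=batch_effects,
        seed=int(rng.integers(2**31 - 1)),
    )
    cal_counts, cal_meta, cal_truth = simulate_calibration(cal_config, basis)

    mock_cols, mock_rows, mock_truth = [], [], {}
    for m in range(n_mock):
        a_m = draw_constrained_composition(D, max_fold, rng)
        expected = closure(a_m.parts * true_b**study_cycles)
        sid = f"mock{m + 1:02d}"
        batch = batches[m % len(batches)]
        bclr = batch_effects.get(batch) if batch_effects else None
        y = _sample_counts(expected, noise_L, bclr, depth, basis, rng)
        mock_cols.append(y)
        mock_rows.append(
            {"sample_id": sid, "cycle": study_cycles, "group": sid, "batch": batch}
        )
        mock_truth[sid] = {"true_a": a_m, "expected_amplified": expected}

    counts = CountTable(
        np.hstack([cal_counts.counts, np.array(mock_cols).T]),
        cal_counts.taxa,
        cal_counts.samples + tuple(r["sample_id"] for r in mock_rows),
    )
    meta = SampleMetadata(pd.concat([cal_meta.table, pd.DataFrame(mock_rows).set_index("sample_id")]))
    truth = {
        "true_b": true_b,
        "true_beta": basis.psi @ np.log(true_b),
        "basis": basis,
        "calibration": cal_truth,
        "mocks": mock_truth,
        "study_cycles": study_cycles,
        "seed": seed,
    }
    return MockStudy(counts=counts, metadata=meta, truth=truth)


def simulate_from_generative(
    prior: PriorSpec,
    design: DesignMatrix,
    depth: int,
    basis: ContrastBasis | None = None,
    seed: int = 0,
) -> tuple[CountTable, dict]:
    """Draw a dataset from the model's own generative process.

    Sigma ~ IW(Xi, upsilon); Lambda ~ MN(Theta, Sigma, Gamma);
    eta_i ~ N(Lambda X_i, Sigma); Y_i ~ Multinomial(depth, phi^-1(eta_i)).
    Used for prior-predictive checks and posterior-coverage studies.
    """
    P = prior.P
    if basis is None:
        basis = alr_basis(P + 1)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.atleast_2d(stats.invwishart.rvs(df=prior.upsilon, scale=prior.xi, random_state=rng))
    chol_sigma = linalg.cholesky(sigma, lower=True)
    chol_gamma = linalg.cholesky(prior.gamma, lower=True)
    lam = prior.theta + chol_sigma @ rng.standard_normal((P, prior.Q)) @ chol_gamma.T
    eta = lam @ design.x + chol_sigma @ rng.standard_normal((P, design.N))
    pi = logratio_to_proportions(eta.T, basis)  # (N, D)
    if depth == 0:
        Y = np.zeros((P + 1, design.N), dtype=np.int64)
    else:
        Y = np.array([rng.multinomial(depth, pi[i]) for i in range(design.N)]).T
    taxa = tuple(f"taxon_{j + 1}" for j in range(P + 1))
    samples = tuple(f"s{i + 1}" for i in range(design.N))
    table = CountTable(Y, taxa, samples)
    return table, {"lambda": lam, "sigma": sigma, "eta": eta, "basis": basis}


def write_bundle(study: MockStudy, out_dir: str | Path) -> None:
    """Write a study bundle: counts.tsv, metadata.tsv, truth.npz, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, out / "counts.tsv")
    write_metadata(study.metadata, out / "metadata.tsv")
    t = study.truth
    np.savez_compressed(
        out / "truth.npz",
        true_b=t["true_b"],
        true_beta=t["true_beta"],
        basis_psi=t["basis"].psi,
        basis_rinv=t["basis"].psi_rinv,
        study_cycles=t["study_cycles"],
        seed=t["seed"],
        **{f"mock_a_{k}": v["true_a"].parts for k, v in t["mocks"].items()},
    )
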