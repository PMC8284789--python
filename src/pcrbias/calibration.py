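"""The PCR bias calibration workflow.

A calibration experiment splits one pooled DNA sample into aliquots, runs
each for a different number of PCR cycles, and sequences them alongside the
study samples. Regressing log-ratio composition on cycle number then gives:

* the intercept alpha_g = Psi log(a): the group's composition before
  amplification (cycle 0);
* the slope beta = Psi log(b): the per-cycle compositional bias driven by
  unequal amplification efficiencies b_j;
* batch terms gamma_b for each non-reference PCR machine.

Correction removes the estimated cycle-indexed perturbation from study
samples, draw-wise, propagating posterior uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mlnl
from .composition import (
    Composition,
    ContrastBasis,
    alr_to_clr,
    clr,
    logratio_to_proportions,
)
from .count_data import CountTable, SampleMetadata

__all__ = [
    "CalibrationDesign",
    "BiasEstimate",
    "build_design",
    "estimate_bias",
    "composition_at_cycle",
    "bias_fold_change",
    "bias_clr",
    "correct_composition",
    "reference_correction",
    "apply_reference_correction",
]


@dataclass(frozen=True)
class CalibrationDesign:
    """Design matrix with bookkeeping for groups, cycle and batches.

    Row order is [group indicators..., cycle, batch indicators...]; the first
    batch (sorted order) is the reference level and gets no column.
    """

    design: mlnl.DesignMatrix
    group_names: tuple[str, ...]
    batch_names: tuple[str, ...]  # non-reference batches, column order
    reference_batch: str
    cycle_column: int

    @property
    def Q(self) -> int:
        return self.design.Q


def build_design(
    metadata: SampleMetadata,
    samples: tuple[str, ...],
    groups: list[str] | None = None,
    batches: list[str] | None = None,
) -> CalibrationDesign:
    """Build the calibration design matrix from sample metadata.

    One 0/1 intercept column per group, the raw (uncentered) cycle count, and
    0/1 indicators for every batch except the first, which serves as the
    reference level. Cycle is left uncentered so that the intercept means
    "cycle 0 = unamplified".
    """
    table = metadata.for_samples(samples)
    if table[["cycle", "group", "batch"]].isna().any().any():
        raise ValueError("every sample needs cycle, group and batch metadata")
    obs_groups = list(dict.fromkeys(table["group"]))
    obs_batches = sorted(set(table["batch"].astype(str)))
    if groups is None:
        groups = obs_groups
    if batches is None:
        batches = obs_batches
    unknown_g = set(table["group"]) - set(groups)
    unknown_b = set(table["batch"].astype(str)) - set(batches)
    if unknown_g:
        raise KeyError(f"metadata contains unknown groups: {sorted(unknown_g)}")
    if unknown_b:
        raise KeyError(f"metadata contains unknown batches: {sorted(unknown_b)}")

    G, N = len(groups), len(samples)
    ref_batch, other_batches = batches[0], list(batches[1:])
    B1 = len(other_batches)
    X = np.zeros((G + 1 + B1, N))
    for i, sid in enumerate(samples):
        row = table.loc[sid]
        X[groups.index(row["group"]), i] = 1.0
        X[G, i] = float(row["cycle"])
        b = str(row["batch"])
        if b != ref_batch:
            X[G + 1 + other_batches.index(b), i] = 1.0
    roles = ("group_intercept",) * G + ("cycle",) + ("batch",) * B1
    labels = tuple(groups) + ("cycle",) + tuple(other_batches)
    return CalibrationDesign(
        design=mlnl.DesignMatrix(X, roles, labels),
        group_names=tuple(groups),
        batch_names=tuple(other_batches),
        reference_batch=ref_batch,
        cycle_column=G,
    )


@dataclass(frozen=True)
class BiasEstimate:
    """Posterior draws of the calibration model's interpretable pieces."""

    alpha_draws: np.ndarray  # (S, P, G) per-group cycle-0 intercepts
    beta_draws: np.ndarray  # (S, P) per-cycle bias
    gamma_draws: np.ndarray  # (S, P, B-1) batch terms
    basis: ContrastBasis
    taxa: tuple[str, ...]
    group_names: tuple[str, ...]
    batch_names: tuple[str, ...]
    fit: mlnl.PosteriorFit | None = None
    beta_mean: np.ndarray | None = None  # Rao-Blackwellized E[beta | Y]
    alpha_mean: np.ndarray | None = None  # (P, G)

    @property
    def n_draws(self) -> int:
        return self.beta_draws.shape[0]

    def group_index(self, group: str) -> int:
        if group not in self.group_names:
            raise KeyError(f"unknown group {group!r}; have {self.group_names}")
        return self.group_names.index(group)


def estimate_bias(
    counts: CountTable,
    cdesign: CalibrationDesign,
    prior: mlnl.PriorSpec | None = None,
    basis: ContrastBasis | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> BiasEstimate:
    """Fit the calibration model and slice the coefficient posterior.

    Wraps the multinomial logistic-normal fit; the Lambda draws are split by
    design-row role into intercepts (alpha), per-cycle bias (beta) and batch
    terms (gamma). Counts should already be filtered (read-depth and rare-
    taxon preprocessing).
    """
    cycle_vals = np.unique(cdesign.design.x[cdesign.cycle_column])
    if cycle_vals.size < 2:
        raise ValueError(
            "slope is unidentifiable: calibration needs at least two distinct cycle numbers"
        )
    fit = mlnl.fit(counts, cdesign.design, prior=prior, basis=basis,
                   n_draws=n_draws, seed=seed)
    lam = fit.lambda_draws
    g_idx = cdesign.design.rows_with_role("group_intercept")
    b_idx = cdesign.design.rows_with_role("batch")
    lam_mean = mlnl.posterior_mean_lambda(fit.eta_draws, fit.design, fit.prior)
    return BiasEstimate(
        alpha_draws=lam[:, :, g_idx],
        beta_draws=lam[:, :, cdesign.cycle_column],
        gamma_draws=lam[:, :, b_idx] if b_idx else np.zeros(lam.shape[:2] + (0,)),
        basis=fit.basis,
        taxa=counts.taxa,
        group_names=cdesign.group_names,
        batch_names=cdesign.batch_names,
        fit=fit,
        beta_mean=lam_mean[:, cdesign.cycle_column],
        alpha_mean=lam_mean[:, g_idx],
    )


def composition_at_cycle(bias: BiasEstimate, group: str, x: float) -> np.ndarray:
    """Posterior draws of a group's composition after x cycles, (S, D).

    Computed as the inverse log-ratio transform of alpha_g + beta * x with
    batch terms at the reference level (zero). x = 0 gives the inferred
    unamplified composition.
    """
    g = bias.group_index(group)
    eta = bias.alpha_draws[:, :, g] + bias.beta_draws * x
    return logratio_to_proportions(eta, bias.basis)


def bias_fold_change(bias: BiasEstimate, group: str, x: float = 35.0) -> np.ndarray:
    """Per-taxon log2 fold change in proportion after x cycles, (S, D).

    log2 pi_j(x) - log2 pi_j(0): +2 means the taxon is over-represented by a
    factor of 4 after x cycles. Not linear in beta because closure
    renormalizes the proportions.
    """
    p_x = composition_at_cycle(bias, group, x)
    p_0 = composition_at_cycle(bias, group, 0.0)
    return np.log2(p_x) - np.log2(p_0)


def bias_clr(bias: BiasEstimate, x: float = 35.0) -> np.ndarray:
    """Per-taxon CLR-scale bias after x cycles, (S, D).

    clr(pi(x)) - clr(pi(0)) equals the CLR representation of x * beta exactly
    (perturbation is linear on the log-ratio scale), so this is group-free
    and sums to zero across taxa in every draw.
    """
    return alr_to_clr(bias.beta_draws * x, bias.basis)


def correct_composition(
    observed: Composition | np.ndarray,
    bias: BiasEstimate,
    x: float,
) -> np.ndarray:
    """Remove x cycles of estimated amplification bias from a composition.

    Draw-wise: inverse log-ratio transform of (Psi log observed - beta * x),
    i.e. perturbation by the inverse of the accumulated bias. ``observed``
    may be a single composition or an (S, D) stack of posterior draws
    (matched to the bias draws by index). Compositions with zeros cannot be
    corrected directly; infer them with the model first.
    """
    if isinstance(observed, Composition):
        obs = observed.parts[None, :]
    else:
        obs = np.atleast_2d(np.asarray(observed, dtype=float))
        if np.any(obs <= 0):
            raise ValueError(
                "observed composition has zero/negative parts; correct via "
                "model-inferred compositions instead of raw proportions"
            )
    if obs.shape[-1] != bias.basis.D:
        raise ValueError("taxa dimension mismatch between observation and bias estimate")
    eta_obs = np.log(obs) @ bias.basis.psi.T  # (1 or S, P)
    eta_corr = eta_obs - bias.beta_draws * x
    return logratio_to_proportions(eta_corr, bias.basis)


def reference_correction(
    inferred_draws: np.ndarray, reference: Composition
) -> np.ndarray:
    """Correction vector against an external reference composition.

    delta = clr(reference) - clr(posterior-mean inferred composition); used
    when the calibration sample's nominal composition (e.g. qPCR-based) is
    itself trusted only up to a perturbation. Applying delta maps the
    inferred calibration mean exactly onto the reference.
    """
    draws = np.atleast_2d(np.asarray(inferred_draws, dtype=float))
    if draws.shape[-1] != reference.D:
        raise KeyError("taxa mismatch between draws and reference")
    mean = draws.mean(axis=0)
    mean = mean / mean.sum()
    lm = np.log(mean)
    return clr(reference) - (lm - lm.mean())


def apply_reference_correction(draws: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Perturb composition draws by exp(delta); preserves Aitchison distances."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    out = draws * np.exp(delta)[None, :]
    return out / out.sum(axis=-1, keepdims=True)


def save_bias(bias: BiasEstimate, path: str | Path) -> None:
    """Serialize a BiasEstimate (draws + labels + basis) to one .npz archive."""
    np.savez_compressed(
        path,
        alpha_draws=bias.alpha_draws,
        beta_draws=bias.beta_draws,
        gamma_draws=bias.gamma_draws,
        basis_psi=bias.basis.psi,
        basis_rinv=bias.basis.psi_rinv,
        basis_kind=bias.basis.kind,
        taxa=np.array(bias.taxa),
        group_names=np.array(bias.group_names),
        batch_names=np.array(bias.batch_names),
    )


def load_bias(path: str | Path) -> BiasEstimate:
    z = np.load(path, allow_pickle=False)
    return BiasEstimate(
        alpha_draws=z["alpha_draws"],
        beta_draws=z["beta_draws"],
        gamma_draws=z["gamma_draws"],
        basis=ContrastBasis(z["basis_psi"], z["basis_rinv"], str(z["basis_kind"])),
        taxa=tuple(z["taxa"]),
        group_names=tuple(z["group_names"]),
        batch_names=tuple(z["batch_names"]),
    )


def export_composition_summary(
    draws: np.ndarray, taxa: tuple[str, ...], path: str | Path
) -> pd.DataFrame:
    """Write per-taxon posterior mean and 95% interval of composition draws."""
    draws = np.atleast_2d(draws)
    df = pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "q2.5": np.quantile(draws, 0.025, axis=0),
            "q97.5": np.quantile(draws, 0.975, axis=0),
        },
        index=list(taxa),
    )
    df.to_csv(path, sep="\t", index_label="taxon")
    return df
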