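"""Aitchison-geometry primitives for compositional data.

Relative-abundance data live on the simplex: only ratios between parts carry
information. This module provides the closure operation, additive log-ratio
(ALR) contrast bases, the forward/inverse log-ratio transforms, compositional
perturbation (the group operation of the simplex) and the Aitchison distance.
All internal coordinates use natural logarithms.

A contrast basis is a (D-1) x D matrix ``psi`` whose rows sum to zero, paired
with a D x (D-1) right-inverse ``psi_rinv`` satisfying ``psi @ psi_rinv = I``.
Because ker(psi) = span(1) for a full-rank zero-row-sum contrast, the inverse
transform ``C[exp(psi_rinv @ eta)]`` is independent of the particular
right-inverse chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Composition",
    "ContrastBasis",
    "closure",
    "alr_basis",
    "to_logratio",
    "from_logratio",
    "alr_to_clr",
    "clr",
    "perturb",
    "aitchison_distance",
]

_TOL = 1e-9


@dataclass(frozen=True)
class Composition:
    """A point on the open simplex: D strictly positive parts summing to 1."""

    parts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        parts = np.asarray(self.parts, dtype=float)
        object.__setattr__(self, "parts", parts)
        if parts.ndim != 1 or parts.size < 2:
            raise ValueError("a composition needs at least two parts")
        if np.any(parts <= 0) or not np.all(np.isfinite(parts)):
            raise ValueError("composition parts must be strictly positive and finite")
        if abs(parts.sum() - 1.0) > _TOL:
            raise ValueError(f"parts must sum to 1 (got {parts.sum():.12g})")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != parts.size:
                raise ValueError("labels length must match number of parts")
            object.__setattr__(self, "labels", labels)

    @property
    def D(self) -> int:
        return self.parts.size


@dataclass(frozen=True)
class ContrastBasis:
    """Log-ratio coordinate system: contrast matrix and a right-inverse.

    ``kind`` tags the provenance of the basis: ``"alr"`` for additive
    log-ratio bases built by :func:`alr_basis`, ``"clr-derived"`` or
    ``"custom"`` otherwise.
    """

    psi: np.ndarray
    psi_rinv: np.ndarray
    kind: str = "custom"
    ref_index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        rinv = np.asarray(self.psi_rinv, dtype=float)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "psi_rinv", rinv)
        dm1, d = psi.shape
        if d != dm1 + 1:
            raise ValueError("psi must be (D-1) x D")
        if rinv.shape != (d, dm1):
            raise ValueError("psi_rinv must be D x (D-1)")
        if np.max(np.abs(psi.sum(axis=1))) > _TOL:
            raise ValueError("rows of psi must sum to zero")
        if np.linalg.matrix_rank(psi) != dm1:
            raise ValueError("psi must have rank D-1")
        if np.max(np.abs(psi @ rinv - np.eye(dm1))) > _TOL:
            raise ValueError("psi @ psi_rinv must equal the identity")

    @property
    def D(self) -> int:
        return self.psi.shape[1]


def closure(m: np.ndarray) -> Composition:
    """Normalize a strictly positive vector to the unit simplex."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("closure needs a vector of length >= 2")
    if np.any(m <= 0) or not np.all(np.isfinite(m)):
        raise ValueError("closure requires strictly positive finite entries")
    return Composition(m / m.sum())


def _closure_array(m: np.ndarray, axis: int = -1) -> np.ndarray:
    """Closure on raw arrays (no Composition wrapper); used on draw stacks."""
    m = np.asarray(m, dtype=float)
    return m / m.sum(axis=axis, keepdims=True)


def alr_basis(D: int, ref_index: int = -1) -> ContrastBasis:
    """Additive log-ratio contrast basis with reference part ``ref_index``.

    Row j of psi carries +1 for the j-th non-reference part and -1 for the
    reference, so coordinate j is log(p_j / p_ref). The right-inverse is the
    "padded" inverse: identity rows for non-reference parts, a zero row for
    the reference.
    """
    if D < 2:
        raise ValueError("need D >= 2")
    if ref_index < 0:
        ref_index += D
    if not 0 <= ref_index < D:
        raise IndexError(f"ref_index {ref_index} out of range for D={D}")
    keep = [j for j in range(D) if j != ref_index]
    psi = np.zeros((D - 1, D))
    rinv = np.zeros((D, D - 1))
    for row, j in enumerate(keep):
        psi[row, j] = 1.0
        psi[row, ref_index] = -1.0
        rinv[j, row] = 1.0
    return ContrastBasis(psi=psi, psi_rinv=rinv, kind="alr", ref_index=ref_index)


def to_logratio(p: Composition, basis: ContrastBasis) -> np.ndarray:
    """Map a composition to its log-ratio coordinates eta = psi @ log(parts)."""
    if p.D != basis.D:
        raise ValueError(f"dimension mismatch: composition D={p.D}, basis D={basis.D}")
    return basis.psi @ np.log(p.parts)


def from_logratio(eta: np.ndarray, basis: ContrastBasis) -> Composition:
    """Invert the log-ratio transform: C[exp(psi_rinv @ eta)]."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    if eta.shape != (basis.D - 1,):
        raise ValueError(f"eta must have length D-1={basis.D - 1}")
    u = basis.psi_rinv @ eta
    u -= u.max()  # overflow guard; closure removes the common factor
    return closure(np.exp(u))


def logratio_to_proportions(eta: np.ndarray, basis: ContrastBasis) -> np.ndarray:
    """Vectorized inverse transform on stacks of coordinates.

    ``eta`` has shape (..., D-1); returns proportions of shape (..., D).
    """
    eta = np.asarray(eta, dtype=float)
    u = eta @ basis.psi_rinv.T
    u -= u.max(axis=-1, keepdims=True)
    return _closure_array(np.exp(u))


def clr(p: Composition) -> np.ndarray:
    """Centered log-ratio: log(parts) minus its mean. Sums to zero."""
    lp = np.log(p.parts)
    return lp - lp.mean()


def alr_to_clr(eta: np.ndarray, basis: ContrastBasis) -> np.ndarray:
    """Re-express log-ratio coordinates in CLR coordinates.

    Works on a single coordinate vector or a stack of draws with coordinates
    on the last axis; each output row sums to zero and implies the same
    composition as the input.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape[-1] != basis.D - 1:
        raise ValueError(f"last axis must have length D-1={basis.D - 1}")
    u = eta @ basis.psi_rinv.T  # log-parts up to an additive constant
    return u - u.mean(axis=-1, keepdims=True)


def perturb(p: Composition, q: np.ndarray) -> Composition:
    """Compositional perturbation: closure of the elementwise product.

    Perturbation is the group operation of the simplex; PCR bias acts as a
    cycle-indexed perturbation of the template composition.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != p.parts.shape:
        raise ValueError("perturbation vector length must match composition")
    if np.any(q <= 0) or not np.all(np.isfinite(q)):
        raise ValueError("perturbation entries must be strictly positive")
    return Composition(p.parts * q / np.sum(p.parts * q), labels=p.labels)


def aitchison_distance(x: Composition, y: Composition) -> float:
    """Euclidean distance between the CLR representations of two compositions."""
    if x.D != y.D:
        raise ValueError("compositions must share dimension")
    return float(np.linalg.norm(clr(x) - clr(y)))
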