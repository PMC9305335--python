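"""Measurement contexts and changes of basis.

A *measurement context* is an ordered orthonormal basis of the model's
Hilbert space; each basis vector spans the ray of one elementary outcome
(e.g. the prediction outcomes P1, P2 of a top-down context, or the evidence
outcomes E1, E2 of a bottom-up context).  All bases are stored as coordinate
rows in a single designated *reference frame*, whose own basis is the
canonical one.

The unitary overlap matrix between two contexts — entry (i, j) equal to the
transition amplitude ⟨A_i|B_j⟩ — converts coordinates between frames and
carries the transition probabilities as its squared magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import IncompatibleModelError, InvalidContextError
from .statespace import PureState

logger = logging.getLogger(__name__)

#: Orthonormality tolerance for the Gram matrix of a context's basis.
GRAM_TOL = 1e-6
#: Basis rows whose norm is within this window of 1 are rescaled (with a
#: logged notice); rows further away are rejected.  Accommodates bases given
#: to a few printed decimals without silently re-orthogonalizing directions.
RENORM_WINDOW = 1e-3


def _as_amplitude_array(values, *, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise InvalidContextError(f"{name}: empty")
    if np.iscomplexobj(arr):
        arr = arr.astype(np.complex128)
        if np.allclose(arr.imag, 0.0, atol=0.0):
            arr = arr.real
    else:
        arr = arr.astype(np.float64)
    return arr


@dataclass(frozen=True)
class MeasurementContext:
    """An ordered orthonormal basis with labelled outcomes.

    Parameters
    ----------
    id
        Context label, e.g. ``"P"`` (prediction) or ``"E"`` (evidence).
    basis
        ``(N, N)`` array; row ``i`` is the coordinate vector of outcome ``i``
        in the model's reference frame.
    labels
        One human-facing label per outcome (1-based by convention: "P1"...).
    is_reference
        True for the single context whose basis is the canonical one.
    """

    id: str
    basis: np.ndarray = field(repr=False)
    labels: tuple[str, ...]
    is_reference: bool = False

    @property
    def dimension(self) -> int:
        return self.basis.shape[0]

    def outcome_index(self, label: str) -> int:
        """Map an outcome label (or a numeric string/0-based int) to its index."""
        if label in self.labels:
            return self.labels.index(label)
        raise KeyError(f"context {self.id!r} has no outcome {label!r}; "
                       f"known labels: {', '.join(self.labels)}")

    def gram_deviation(self) -> float:
        """Max entrywise deviation of the basis Gram matrix from identity."""
        gram = np.conj(self.basis) @ self.basis.T
        return float(np.max(np.abs(gram - np.eye(self.dimension))))


def build_context(
    id: str,
    vectors,
    labels: Sequence[str] | None = None,
    *,
    is_reference: bool = False,
    tol: float = GRAM_TOL,
) -> MeasurementContext:
    """Validated constructor for a measurement context.

    Rows within :data:`RENORM_WINDOW` of unit norm are rescaled (logged when
    the deviation exceeds ``tol``); after that the Gram matrix must equal the
    identity within ``tol``, otherwise :class:`InvalidContextError` is raised
    — directions are never repaired.
    """
    basis = _as_amplitude_array(vectors, name=f"context {id!r} basis")
    if basis.ndim != 2 or basis.shape[0] != basis.shape[1]:
        raise InvalidContextError(
            f"context {id!r}: expected N vectors of length N, got shape {basis.shape}")
    n = basis.shape[0]
    if n < 2:
        raise InvalidContextError(f"context {id!r}: dimension must be >= 2, got {n}")

    norms = np.linalg.norm(basis, axis=1)
    if np.any(np.abs(norms - 1.0) > RENORM_WINDOW):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise InvalidContextError(
            f"context {id!r}: basis vector {bad} has norm {norms[bad]:.6g}, "
            f"further than {RENORM_WINDOW} from 1")
    if np.any(np.abs(norms - 1.0) > tol):
        logger.info("context %r: renormalizing basis rows (max norm deviation %.3g)",
                    id, float(np.max(np.abs(norms - 1.0))))
    basis = basis / norms[:, None]

    gram = np.conj(basis) @ basis.T
    dev = float(np.max(np.abs(gram - np.eye(n))))
    if dev > tol:
        raise InvalidContextError(
            f"context {id!r}: basis not orthonormal (Gram deviation {dev:.3g} > {tol:g})")

    if labels is None:
        labels = tuple(f"{id}{k + 1}" for k in range(n))
    else:
        labels = tuple(str(lb) for lb in labels)
        if len(labels) != n:
            raise InvalidContextError(
                f"context {id!r}: {len(labels)} labels for {n} outcomes")
        if len(set(labels)) != n:
            raise InvalidContextError(f"context {id!r}: duplicate outcome labels")

    basis.setflags(write=False)
    return MeasurementContext(id=id, basis=basis, labels=labels,
                              is_reference=is_reference)


def canonical_context(id: str, dimension: int,
                      labels: Sequence[str] | None = None,
                      *, is_reference: bool = True) -> MeasurementContext:
    """The context whose basis vectors are the canonical unit vectors."""
    return build_context(id, np.eye(dimension), labels, is_reference=is_reference)


@dataclass(frozen=True)
class TransitionMatrix:
    """Unitary of pairwise transition amplitudes between two contexts.

    ``entries[i, j] = ⟨A_i|B_j⟩`` where A is the *from* context and B the
    *to* context.  Its conjugate transpose is the reverse-direction matrix,
    and the matrix of squared magnitudes is doubly stochastic.
    """

    from_context: str
    to_context: str
    entries: np.ndarray = field(repr=False)

    @property
    def dimension(self) -> int:
        return self.entries.shape[0]

    def dagger(self) -> "TransitionMatrix":
        """The reverse-direction (conjugate-transpose) matrix."""
        return TransitionMatrix(self.to_context, self.from_context,
                                np.conj(self.entries.T))

    def unitarity_deviation(self) -> float:
        n = self.dimension
        return float(np.max(np.abs(self.entries @ np.conj(self.entries.T) - np.eye(n))))

    def squared_magnitudes(self) -> np.ndarray:
        """Transition-probability matrix |⟨A_i|B_j⟩|² (doubly stochastic)."""
        return np.abs(self.entries) ** 2


def transition_matrix(ctx_a: MeasurementContext,
                      ctx_b: MeasurementContext) -> TransitionMatrix:
    """Overlap matrix between two contexts sharing the reference frame."""
    if ctx_a.dimension != ctx_b.dimension:
        raise IncompatibleModelError(
            f"contexts {ctx_a.id!r} ({ctx_a.dimension}-D) and {ctx_b.id!r} "
            f"({ctx_b.dimension}-D) have different dimensions")
    entries = np.conj(ctx_a.basis) @ ctx_b.basis.T
    return TransitionMatrix(ctx_a.id, ctx_b.id, entries)


def change_frame(state: PureState, to_context: MeasurementContext,
                 from_context: MeasurementContext) -> PureState:
    """Re-express a state's coordinates in another context's frame.

    The physical state is unchanged: Born probabilities of every fixed event
    are preserved (the conversion is unitary).
    """
    if state.frame != from_context.id:
        raise IncompatibleModelError(
            f"state is expressed in frame {state.frame!r}, not {from_context.id!r}")
    if state.coords.shape[0] != from_context.dimension:
        raise IncompatibleModelError(
            f"state has {state.coords.shape[0]} coordinates but context "
            f"{from_context.id!r} is {from_context.dimension}-dimensional")
    if from_context.dimension != to_context.dimension:
        raise IncompatibleModelError(
            f"contexts {from_context.id!r} and {to_context.id!r} have different dimensions")
    # Reference-frame coordinates of the state, then project on target rows.
    ref = from_context.basis.T @ state.coords
    coords = np.conj(to_context.basis) @ ref
    return PureState(coords=coords, frame=to_context.id)


def ray_equivalent(ctx_a: MeasurementContext, ctx_b: MeasurementContext,
                   *, tol: float = 1e-9) -> bool:
    """True iff each outcome vector of B equals the same-index vector of A up
    to a unit phase (sign, for real bases).

    Outcome order matters: permuted bases relabel outcomes and are *not*
    equivalent.  Ray-equivalent contexts yield identical probability tables
    for every state.
    """
    if ctx_a.dimension != ctx_b.dimension:
        return False
    for a, b in zip(ctx_a.basis, ctx_b.basis):
        phase = np.vdot(a, b)  # ⟨a|b⟩; unit modulus iff b = phase·a
        if abs(abs(phase) - 1.0) > tol:
            return False
        if np.max(np.abs(b - phase * a)) > tol:
            return False
    return True
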