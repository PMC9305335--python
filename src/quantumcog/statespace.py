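"""Pure states, events, Born-rule probabilities, collapse and sampling.

The cognitive state is a unit vector |S⟩ in an N-dimensional Hilbert space.
Its coordinates depend on the measurement context (frame) they are written
in; the Born rule turns squared projection lengths into outcome
probabilities, and a registered outcome projects the state onto the event's
subspace and renormalizes it (Lüders collapse).

Amplitudes may be real or complex; the worked examples in the tests are
real, matching the stylized two-context model this package ships.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .errors import (
    ImpossibleOutcomeError,
    IncompatibleModelError,
    MalformedStateError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard (frames imports us)
    from .frames import MeasurementContext

logger = logging.getLogger(__name__)

#: Default tolerance on |‖ψ‖² − 1| for state validation.
NORM_TOL = 1e-6
#: States whose squared norm is within this window of 1 are renormalized on
#: construction (logged); beyond it construction fails.
RENORM_WINDOW = 1e-3
#: Events with Born probability at or below this threshold cannot be
#: collapsed onto (the post-measurement direction would be numerical noise).
COLLAPSE_EPS = 1e-12


@dataclass(frozen=True)
class PureState:
    """A state vector: ordered amplitudes plus the frame they refer to.

    The dataclass itself performs no validation so that out-of-norm vectors
    can be represented and *reported* on; use :func:`pure_state` to construct
    a checked, normalized state.
    """

    coords: np.ndarray = field(repr=False)
    frame: str

    @property
    def dimension(self) -> int:
        return int(np.asarray(self.coords).shape[0])

    def norm_squared(self) -> float:
        return float(np.real(np.vdot(self.coords, self.coords)))


@dataclass(frozen=True)
class EventSubspace:
    """A measurement event: a context plus a nonempty set of outcome indices.

    A single index is a ray (elementary outcome); several indices form a
    union event spanned by the corresponding basis vectors; the full index
    set is the sure event.
    """

    context: "MeasurementContext"
    outcomes: frozenset[int]

    @property
    def is_ray(self) -> bool:
        return len(self.outcomes) == 1

    @property
    def sorted_outcomes(self) -> tuple[int, ...]:
        return tuple(sorted(self.outcomes))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.context.labels[i] for i in self.sorted_outcomes)

    def __str__(self) -> str:  # e.g. "E:E2" or "P:P1+P2"
        return f"{self.context.id}:{'+'.join(self.labels)}"


@dataclass(frozen=True)
class StateValidationReport:
    ok: bool
    norm_squared: float
    tol: float


def pure_state(coords, frame: str, *, tol: float = NORM_TOL) -> PureState:
    """Checked constructor: validates shape and norm, renormalizes within
    :data:`RENORM_WINDOW` (logged when the deviation exceeds ``tol``)."""
    arr = np.asarray(coords)
    if arr.size == 0:
        raise MalformedStateError("state has no coordinates")
    if arr.ndim != 1:
        raise MalformedStateError(f"state coordinates must be 1-D, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise MalformedStateError("state dimension must be >= 2")
    if np.iscomplexobj(arr):
        arr = arr.astype(np.complex128)
        if np.allclose(arr.imag, 0.0, atol=0.0):
            arr = arr.real
    else:
        arr = arr.astype(np.float64)
    nsq = float(np.real(np.vdot(arr, arr)))
    if abs(nsq - 1.0) > RENORM_WINDOW:
        raise MalformedStateError(
            f"state squared norm {nsq:.6g} is further than {RENORM_WINDOW} from 1")
    if abs(nsq - 1.0) > tol:
        logger.info("state in frame %r renormalized (‖ψ‖² was %.6g)", frame, nsq)
    arr = arr / np.sqrt(nsq)
    arr.setflags(write=False)
    return PureState(coords=arr, frame=frame)


def validate_state(state: PureState, tol: float = NORM_TOL) -> StateValidationReport:
    """Report whether ‖ψ‖² equals 1 within ``tol`` (no mutation)."""
    arr = np.asarray(state.coords)
    if arr.size == 0:
        raise MalformedStateError("state has no coordinates")
    nsq = float(np.real(np.vdot(arr, arr)))
    return StateValidationReport(ok=abs(nsq - 1.0) <= tol, norm_squared=nsq, tol=tol)


def event(context: "MeasurementContext", outcomes: Iterable[int] | int) -> EventSubspace:
    """Checked constructor for an event subspace (0-based outcome indices)."""
    if isinstance(outcomes, (int, np.integer)):
        outcomes = (int(outcomes),)
    idx = frozenset(int(i) for i in outcomes)
    if not idx:
        raise ValueError("event needs at least one outcome index")
    n = context.dimension
    bad = [i for i in idx if not 0 <= i < n]
    if bad:
        raise ValueError(f"outcome indices {bad} out of range [0, {n}) for context "
                         f"{context.id!r}")
    return EventSubspace(context=context, outcomes=idx)


def _context_amplitudes(state: PureState, target: "MeasurementContext",
                        state_context: "MeasurementContext | None") -> np.ndarray:
    """Coordinates ⟨F_i|S⟩ of the state in the target context's frame."""
    coords = np.asarray(state.coords)
    if state.frame == target.id:
        if coords.shape[0] != target.dimension:
            raise IncompatibleModelError(
                f"state has {coords.shape[0]} coordinates but context "
                f"{target.id!r} is {target.dimension}-dimensional")
        return coords
    if state_context is None:
        raise IncompatibleModelError(
            f"state is expressed in frame {state.frame!r}; pass that context to "
            f"relate it to context {target.id!r}")
    if state_context.id != state.frame:
        raise IncompatibleModelError(
            f"state frame {state.frame!r} does not match supplied context "
            f"{state_context.id!r}")
    if state_context.dimension != target.dimension:
        raise IncompatibleModelError(
            f"contexts {state_context.id!r} and {target.id!r} have different dimensions")
    if coords.shape[0] != state_context.dimension:
        raise IncompatibleModelError(
            f"state has {coords.shape[0]} coordinates but context "
            f"{state_context.id!r} is {state_context.dimension}-dimensional")
    ref = state_context.basis.T @ coords
    return np.conj(target.basis) @ ref


def transition_amplitude(state: PureState, ev: EventSubspace,
                         state_context: "MeasurementContext | None" = None):
    """Inner product ⟨outcome|S⟩ for a single-ray event.

    Its squared magnitude is the transition probability from the state to
    that outcome.
    """
    if not ev.is_ray:
        raise ValueError("transition_amplitude is defined for single-ray events; "
                         "use born_probability for unions")
    amps = _context_amplitudes(state, ev.context, state_context)
    (i,) = ev.outcomes
    a = amps[i]
    return complex(a) if np.iscomplexobj(amps) else float(a)


def born_probability(state: PureState, ev: EventSubspace,
                     state_context: "MeasurementContext | None" = None,
                     *, tol: float = NORM_TOL) -> float:
    """Squared length of the projection of the state onto the event subspace.

    For a union of rays from one context this equals the sum of the per-ray
    probabilities (the rays are orthogonal).
    """
    report = validate_state(state, tol=tol)
    if not report.ok:
        raise MalformedStateError(
            f"state is not normalized (‖ψ‖² = {report.norm_squared:.6g})")
    amps = _context_amplitudes(state, ev.context, state_context)
    p = float(np.sum(np.abs(amps[list(ev.sorted_outcomes)]) ** 2))
    return min(max(p, 0.0), 1.0)


def _fix_phase(coords: np.ndarray) -> np.ndarray:
    """Deterministic global phase: the largest-magnitude amplitude is made
    real and nonnegative (lowest index on ties).  Probabilities unaffected."""
    k = int(np.argmax(np.round(np.abs(coords), decimals=15)))
    a = coords[k]
    if abs(a) == 0.0:
        return coords
    phase = a / abs(a)
    out = coords / phase
    if not np.iscomplexobj(coords):
        out = out.astype(np.float64)
    elif np.allclose(out.imag, 0.0, atol=1e-15):
        out = out.real
    return out


def collapse(state: PureState, ev: EventSubspace,
             state_context: "MeasurementContext | None" = None,
             *, eps: float = COLLAPSE_EPS) -> PureState:
    """Post-measurement state after registering the event (Lüders rule).

    The state is projected onto the event's subspace and divided by the
    projection length; the result lies entirely in that subspace.  For a ray
    the result is the outcome's basis vector (phase fixed real-nonnegative).
    The returned coordinates are expressed in the input state's frame.

    Raises
    ------
    ImpossibleOutcomeError
        If the event's Born probability is at or below ``eps``.
    """
    p = born_probability(state, ev, state_context)
    if p <= eps:
        raise ImpossibleOutcomeError(
            f"cannot collapse onto {ev}: probability {p:.3g} <= {eps:g}")
    amps = _context_amplitudes(state, ev.context, state_context)
    projected = np.zeros_like(amps)
    idx = list(ev.sorted_outcomes)
    projected[idx] = amps[idx]
    projected = _fix_phase(projected / np.sqrt(p))
    if state.frame == ev.context.id:
        out = projected
    else:
        # back through the reference frame into the original frame
        ref = ev.context.basis.T @ projected
        out = np.conj(state_context.basis) @ ref  # type: ignore[union-attr]
    out = np.array(out)
    out.setflags(write=False)
    return PureState(coords=out, frame=state.frame)


def probability_table(state: PureState, context: "MeasurementContext",
                      state_context: "MeasurementContext | None" = None) -> pd.DataFrame:
    """Born distribution over a context's outcomes as a tidy table
    (columns: context, outcome, probability)."""
    amps = _context_amplitudes(state, context, state_context)
    probs = np.abs(amps) ** 2
    return pd.DataFrame({
        "context": context.id,
        "outcome": list(context.labels),
        "probability": probs,
    })


def sample_outcome(state: PureState, context: "MeasurementContext",
                   n: int, seed: int | np.random.Generator | None = None,
                   state_context: "MeasurementContext | None" = None) -> pd.DataFrame:
    """Monte-Carlo realization of the Born distribution.

    Draws ``n`` i.i.d. outcomes and returns a frequency table (columns:
    context, outcome, count, frequency, probability).  Reproducible for a
    fixed integer seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amps = _context_amplitudes(state, context, state_context)
    probs = np.abs(amps) ** 2
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs)
    return pd.DataFrame({
        "context": context.id,
        "outcome": list(context.labels),
        "count": counts,
        "frequency": counts / n,
        "probability": probs,
    })
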