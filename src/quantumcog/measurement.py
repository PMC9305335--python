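"""Sequential measurements, order effects, interference and compatibility.

The heart of the quantum account of top-down/bottom-up interaction: when
two measurement contexts do not commute, the probability of a sequence of
outcomes depends on their order, and decomposing a direct outcome through an
intermediate context no longer obeys the classical law of total probability.
When the contexts *are* compatible (commuting ray projectors) every quantity
here reduces to its classical Bayesian counterpart: order effects and
interference vanish and collapse-then-measure is ordinary conditioning.

Path semantics are multiplicative: a path probability is the product of the
per-step conditional probabilities obtained by iterated Born rule + Lüders
collapse.  For rank-1 (ray) steps this equals the product of squared
transition amplitudes.  Note a common slip when computing such chains by
hand is to *add* the per-step probabilities; the sum of step probabilities
is reported alongside so the difference is visible, but it is never a
probability of anything.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ImpossibleOutcomeError, IncompatibleModelError
from .frames import MeasurementContext, transition_matrix
from .statespace import (
    COLLAPSE_EPS,
    EventSubspace,
    PureState,
    born_probability,
    collapse,
    event,
    transition_amplitude,
)

logger = logging.getLogger(__name__)

#: Tolerance on projector-commutator entries for the compatibility verdict.
COMMUTATOR_TOL = 1e-9


# ---------------------------------------------------------------------------
# report types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathResult:
    """Outcome of a sequential measurement path.

    ``steps`` lists (context id, outcome indices) in measurement order;
    ``step_probabilities`` are the conditional probabilities given all
    previous collapses; ``path_probability`` is their product.  If a step has
    (numerically) zero probability the path is impossible: the probability is
    0, ``possible`` is False and ``post_state`` is None.  ``coarse`` flags
    paths containing union (rank > 1) steps, a standard projective
    generalization beyond the elementary ray-path model.
    """

    steps: tuple[tuple[str, tuple[int, ...]], ...]
    step_probabilities: tuple[float, ...]
    path_probability: float
    post_state: PureState | None
    possible: bool = True
    coarse: bool = False

    @property
    def step_probability_sum(self) -> float:
        """Sum of per-step probabilities — NOT a path probability (see module
        docstring); exposed to make the product-vs-sum distinction auditable."""
        return float(sum(self.step_probabilities))

    def to_dict(self) -> dict:
        return {
            "steps": [{"context": c, "outcomes": list(o)} for c, o in self.steps],
            "step_probabilities": list(self.step_probabilities),
            "path_probability": self.path_probability,
            "step_probability_sum": self.step_probability_sum,
            "possible": self.possible,
            "coarse": self.coarse,
            "post_state": None if self.post_state is None else {
                "frame": self.post_state.frame,
                "coords": _coords_payload(self.post_state.coords),
            },
        }


@dataclass(frozen=True)
class InterferenceReport:
    """Direct probability vs. its decomposition through an intermediate
    context; a nonzero ``interference_term`` is a violation of the law of
    total probability."""

    final_event: str
    intermediate_context: str
    direct_probability: float
    mediated_probabilities: tuple[float, ...]
    classical_sum: float
    interference_term: float
    direct_amplitude: complex | float | None = None
    mediated_amplitude_sum: complex | float | None = None

    @property
    def amplitude_identity_ok(self) -> bool | None:
        """Completeness check ⟨final|S⟩ = Σ_i ⟨final|i⟩⟨i|S⟩ (rays only)."""
        if self.direct_amplitude is None or self.mediated_amplitude_sum is None:
            return None
        return bool(abs(self.direct_amplitude - self.mediated_amplitude_sum) <= 1e-9)

    def to_dict(self) -> dict:
        return {
            "final_event": self.final_event,
            "intermediate_context": self.intermediate_context,
            "direct": self.direct_probability,
            "mediated": list(self.mediated_probabilities),
            "classical_sum": self.classical_sum,
            "interference": self.interference_term,
            "direct_amplitude": _scalar_payload(self.direct_amplitude),
            "mediated_amplitude_sum": _scalar_payload(self.mediated_amplitude_sum),
            "amplitude_identity_ok": self.amplitude_identity_ok,
        }


@dataclass(frozen=True)
class CompatibilityReport:
    """Do two contexts commute?  ``max_projector_commutator_norm`` is the
    largest entrywise magnitude over all ray-projector commutators; when it
    is (numerically) zero the pair is compatible and sequential measurement
    is classical — the Bayesian limit."""

    contexts: tuple[str, str]
    max_projector_commutator_norm: float
    compatible: bool
    max_order_effect: float | None = None

    def to_dict(self) -> dict:
        return {
            "contexts": list(self.contexts),
            "max_projector_commutator_norm": self.max_projector_commutator_norm,
            "compatible": self.compatible,
            "max_order_effect": self.max_order_effect,
        }


@dataclass(frozen=True)
class ReciprocityReport:
    """Squared-magnitude transition matrix |⟨A_i|B_j⟩|² with its symmetry
    diagnostics: reciprocity (|⟨a|b⟩|² = |⟨b|a⟩|² per ray pair) and double
    stochasticity (rows and columns each sum to 1)."""

    contexts: tuple[str, str]
    matrix: np.ndarray = field(repr=False)
    reciprocal: bool = True
    doubly_stochastic: bool = True
    max_sum_deviation: float = 0.0

    def to_dict(self) -> dict:
        return {
            "contexts": list(self.contexts),
            "matrix": self.matrix.tolist(),
            "reciprocal": self.reciprocal,
            "doubly_stochastic": self.doubly_stochastic,
            "max_sum_deviation": self.max_sum_deviation,
        }


@dataclass(frozen=True)
class BayesReport:
    """Conditioning within one context: collapse on a union U then measure
    must reproduce classical renormalization P(j|U) = P(j)/P(U) for j ∈ U."""

    context: str
    union: tuple[int, ...]
    conditional: tuple[float, ...]
    classical_expected: tuple[float, ...]
    max_deviation: float
    consistent: bool

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "union": list(self.union),
            "conditional": list(self.conditional),
            "classical_expected": list(self.classical_expected),
            "max_deviation": self.max_deviation,
            "consistent": self.consistent,
        }


def _coords_payload(coords: np.ndarray):
    if np.iscomplexobj(coords):
        return [[float(c.real), float(c.imag)] for c in coords]
    return [float(c) for c in coords]


def _scalar_payload(x):
    if x is None:
        return None
    if isinstance(x, complex):
        return [x.real, x.imag]
    return float(x)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def path_probability(state: PureState, steps: Sequence[EventSubspace],
                     state_context: MeasurementContext | None = None,
                     *, eps: float = COLLAPSE_EPS) -> PathResult:
    """Probability of observing a sequence of events, via iterated
    Born rule + collapse (the quantum chain rule).

    Each step's probability is conditional on all previous outcomes; the
    path probability is their product.  A step of (numerically) zero
    probability makes the whole path impossible (probability 0, flagged).
    """
    if len(steps) < 1:
        raise ValueError("a path needs at least one step")
    current = state
    step_probs: list[float] = []
    described = tuple((ev.context.id, ev.sorted_outcomes) for ev in steps)
    coarse = any(not ev.is_ray for ev in steps)
    if coarse:
        logger.info("path contains union (coarse) steps: projective "
                    "generalization beyond elementary ray paths")
    for ev in steps:
        p = born_probability(current, ev, state_context)
        step_probs.append(p)
        if p <= eps:
            return PathResult(steps=described,
                              step_probabilities=tuple(step_probs),
                              path_probability=0.0, post_state=None,
                              possible=False, coarse=coarse)
        current = collapse(current, ev, state_context, eps=eps)
    prob = float(np.prod(step_probs))
    return PathResult(steps=described, step_probabilities=tuple(step_probs),
                      path_probability=prob, post_state=current,
                      possible=True, coarse=coarse)


def order_effect(state: PureState, event_a: EventSubspace, event_b: EventSubspace,
                 state_context: MeasurementContext | None = None) -> float:
    """Signed order effect P(A then B) − P(B then A).

    Antisymmetric in its events; identically zero when the two events'
    contexts are compatible (in particular within a single context).
    Sequential probabilities use iterated collapse, which is the consistent
    definition also for union events.
    """
    p_ab = path_probability(state, [event_a, event_b], state_context).path_probability
    p_ba = path_probability(state, [event_b, event_a], state_context).path_probability
    return p_ab - p_ba


def reciprocity_matrix(ctx_a: MeasurementContext, ctx_b: MeasurementContext,
                       *, tol: float = COMMUTATOR_TOL) -> ReciprocityReport:
    """Transition-probability matrix between two contexts with symmetry
    diagnostics.

    Entry (i, j) is |⟨A_i|B_j⟩|².  The law of reciprocity makes it equal to
    the reverse-direction entry |⟨B_j|A_i⟩|², and unitarity of the amplitude
    matrix makes it doubly stochastic.  Both hold for rays only; union events
    have no such symmetry.
    """
    fwd = transition_matrix(ctx_a, ctx_b).squared_magnitudes()
    rev = transition_matrix(ctx_b, ctx_a).squared_magnitudes()
    reciprocal = bool(np.max(np.abs(fwd - rev.T)) <= tol)
    row_dev = np.abs(fwd.sum(axis=1) - 1.0)
    col_dev = np.abs(fwd.sum(axis=0) - 1.0)
    max_dev = float(max(row_dev.max(), col_dev.max()))
    return ReciprocityReport(contexts=(ctx_a.id, ctx_b.id), matrix=fwd,
                             reciprocal=reciprocal,
                             doubly_stochastic=max_dev <= tol,
                             max_sum_deviation=max_dev)


def _ray_projectors(ctx: MeasurementContext) -> list[np.ndarray]:
    """Rank-1 projectors |b_i⟩⟨b_i| in reference-frame coordinates."""
    return [np.outer(b, np.conj(b)) for b in ctx.basis]


def compatibility_report(ctx_a: MeasurementContext, ctx_b: MeasurementContext,
                         state: PureState | None = None,
                         state_context: MeasurementContext | None = None,
                         *, tol: float = COMMUTATOR_TOL) -> CompatibilityReport:
    """Commutation diagnostics for a pair of contexts.

    Computes every pairwise commutator [Π_i, Π_j] of ray projectors from the
    two contexts; the pair is compatible iff all commutators vanish within
    ``tol``.  If a state is supplied, the largest |order effect| over all ray
    pairs is evaluated for it — zero whenever the verdict is "compatible".
    """
    if ctx_a.dimension != ctx_b.dimension:
        raise IncompatibleModelError(
            f"contexts {ctx_a.id!r} and {ctx_b.id!r} have different dimensions")
    norm = 0.0
    for pa, pb in itertools.product(_ray_projectors(ctx_a), _ray_projectors(ctx_b)):
        comm = pa @ pb - pb @ pa
        norm = max(norm, float(np.max(np.abs(comm))))
    max_oe: float | None = None
    if state is not None:
        max_oe = 0.0
        for i, j in itertools.product(range(ctx_a.dimension), range(ctx_b.dimension)):
            delta = order_effect(state, event(ctx_a, i), event(ctx_b, j), state_context)
            max_oe = max(max_oe, abs(delta))
    return CompatibilityReport(contexts=(ctx_a.id, ctx_b.id),
                               max_projector_commutator_norm=norm,
                               compatible=norm <= tol,
                               max_order_effect=max_oe)


def total_probability_decomposition(
    state: PureState,
    intermediate_context: MeasurementContext,
    final_event: EventSubspace,
    state_context: MeasurementContext | None = None,
) -> InterferenceReport:
    """Compare a direct outcome probability with its classical decomposition
    through a complete intermediate context.

    ``mediated_probabilities[i]`` is the two-step path probability through
    intermediate ray i; their sum is what the law of total probability would
    predict; ``interference_term = direct − classical_sum`` is zero exactly
    when the contexts are compatible and generically nonzero otherwise.  For
    a ray final event the underlying amplitude completeness relation
    ⟨final|S⟩ = Σ_i ⟨final|i⟩⟨i|S⟩ is reported too: the amplitudes always
    add up — the probabilities need not.
    """
    direct = born_probability(state, final_event, state_context)
    mediated = []
    for i in range(intermediate_context.dimension):
        res = path_probability(state, [event(intermediate_context, i), final_event],
                               state_context)
        mediated.append(res.path_probability)
    classical = float(sum(mediated))

    direct_amp = mediated_amp = None
    if final_event.is_ray:
        direct_amp = transition_amplitude(state, final_event, state_context)
        (k,) = final_event.outcomes
        f = final_event.context.basis[k]          # final ray, reference coords
        total = 0.0 + 0.0j
        for i, b in enumerate(intermediate_context.basis):
            amp_fi = np.vdot(f, b)                # ⟨final|i⟩
            amp_is = transition_amplitude(state, event(intermediate_context, i),
                                          state_context)
            total += complex(amp_fi) * complex(amp_is)
        mediated_amp = total.real if abs(total.imag) < 1e-15 else total

    return InterferenceReport(
        final_event=str(final_event),
        intermediate_context=intermediate_context.id,
        direct_probability=direct,
        mediated_probabilities=tuple(mediated),
        classical_sum=classical,
        interference_term=direct - classical,
        direct_amplitude=direct_amp,
        mediated_amplitude_sum=mediated_amp,
    )


def bayes_equivalence_check(state: PureState, context: MeasurementContext,
                            outcomes: Sequence[int] | None = None,
                            state_context: MeasurementContext | None = None,
                            *, tol: float = COMMUTATOR_TOL,
                            eps: float = COLLAPSE_EPS) -> BayesReport:
    """Verify that measurement within a single context is classical
    conditioning.

    Collapsing on the union U and then measuring must give
    P(ray j | U) = P(ray j)/P(U) for j ∈ U and 0 otherwise — Bayes' rule
    with the union as the conditioning event.  This is the commuting
    (compatible) special case of the quantum framework.
    """
    idx = tuple(range(context.dimension)) if outcomes is None else tuple(outcomes)
    union = event(context, idx)
    p_union = born_probability(state, union, state_context)
    if p_union <= eps:
        raise ImpossibleOutcomeError(
            f"union {union} has probability {p_union:.3g}; conditioning undefined")
    collapsed = collapse(state, union, state_context, eps=eps)
    conditional = []
    expected = []
    for j in range(context.dimension):
        ray = event(context, j)
        conditional.append(born_probability(collapsed, ray, state_context))
        pj = born_probability(state, ray, state_context)
        expected.append(pj / p_union if j in union.outcomes else 0.0)
    dev = float(np.max(np.abs(np.array(conditional) - np.array(expected))))
    return BayesReport(context=context.id, union=union.sorted_outcomes,
                       conditional=tuple(conditional),
                       classical_expected=tuple(expected),
                       max_deviation=dev, consistent=dev <= tol)
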