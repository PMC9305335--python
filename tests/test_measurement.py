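"""Sequential paths, order effects, interference, compatibility, Bayes limit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import quantumcog as qc


class TestPathProbability:
    def test_evidence_then_prediction(self, example):
        res = example.path("E:E2,P:P1")
        assert res.possible
        assert res.path_probability == pytest.approx(0.3209, abs=1e-3)
        assert res.step_probabilities[0] == pytest.approx(0.3968, abs=1e-3)
        assert res.step_probabilities[1] == pytest.approx(0.8089, abs=1e-3)

    def test_prediction_then_evidence_uses_product_rule(self, example):
        """The reverse path is the product 0.0515 · 0.8089 ≈ 0.0416; adding
        the step probabilities instead (≈ 0.8604) is not a probability."""
        res = example.path("P:P1,E:E2")
        assert res.path_probability == pytest.approx(0.0416, abs=1e-3)
        assert res.path_probability == pytest.approx(
            math.prod(res.step_probabilities), abs=1e-12)
        assert res.step_probability_sum == pytest.approx(0.8604, abs=1e-3)
        assert abs(res.path_probability - 0.8604) > 0.5

    def test_repeated_step_is_idempotent(self, example):
        single = example.path("P:P1").path_probability
        double = example.path("P:P1,P:P1")
        assert double.path_probability == pytest.approx(single, abs=1e-12)
        assert double.step_probabilities[1] == pytest.approx(1.0, abs=1e-12)

    def test_impossible_path_flagged(self, example):
        res = example.path("P:P1,P:P2")  # orthogonal rays in one context
        assert not res.possible
        assert res.path_probability == 0.0
        assert res.post_state is None

    def test_path_probability_bounded_by_min_step(self, example):
        res = example.path("E:E2,P:P1")
        assert 0.0 <= res.path_probability <= min(res.step_probabilities)

    def test_union_steps_flagged_coarse(self, example):
        res = example.path(["E:E1+E2", "P:P1"])
        assert res.coarse
        # sure-event first step leaves the state untouched
        assert res.path_probability == pytest.approx(
            example.born_probability("P:P1"), abs=1e-12)

    def test_empty_path_rejected(self, example):
        with pytest.raises(ValueError):
            example.path([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 200_000), dim=st.integers(2, 4))
    def test_iterated_collapse_equals_amplitude_product_oracle(self, seed, dim):
        """For rank-1 paths the chain of Born+collapse equals the product of
        squared transition amplitudes, computed here independently from raw
        basis vectors."""
        m = qc.random_model(dim, 3, seed=seed)
        rng = np.random.default_rng(seed + 1)
        ids = list(m.contexts)
        steps, vectors = [], []
        for _ in range(3):
            cid = ids[rng.integers(len(ids))]
            k = int(rng.integers(dim))
            steps.append(qc.event(m.context(cid), k))
            vectors.append(m.context(cid).basis[k])
        res = qc.path_probability(m.state, steps, m.state_context)
        prev = m.state.coords  # reference frame == state frame C1
        expected = 1.0
        for v in vectors:
            amp = np.vdot(v, prev)
            expected *= abs(amp) ** 2
            prev = v
        if expected <= 1e-12:
            assert res.path_probability <= 1e-9
        else:
            assert res.path_probability == pytest.approx(expected, abs=1e-12)


class TestOrderEffect:
    def test_worked_example_signed_delta(self, example):
        delta = example.order_effect("E:E2", "P:P1")
        assert delta == pytest.approx(0.3209 - 0.0416, abs=2e-3)

    def test_same_context_no_order_effect(self, example):
        assert example.order_effect("P:P1", "P:P2") == 0.0

    def test_antisymmetry(self, example):
        ab = example.order_effect("E:E2", "P:P1")
        ba = example.order_effect("P:P1", "E:E2")
        assert ab == pytest.approx(-ba, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_identical_contexts_never_show_order_effects(self, seed):
        m = qc.random_model(3, 2, seed=seed)
        ctx = m.context("C2")
        twin = qc.build_context("T", ctx.basis)
        for i in range(3):
            for j in range(3):
                delta = qc.order_effect(m.state, qc.event(ctx, i),
                                        qc.event(twin, j), m.state_context)
                assert delta == pytest.approx(0.0, abs=1e-12)


class TestReciprocity:
    def test_worked_example_entry_and_symmetry(self, example):
        rep = example.reciprocity("P", "E")
        assert rep.matrix[0, 1] == pytest.approx(0.8089, abs=1e-3)
        assert rep.reciprocal
        assert rep.doubly_stochastic
        rev = example.reciprocity("E", "P")
        assert rep.matrix == pytest.approx(rev.matrix.T, abs=1e-12)

    def test_identity_pair(self, ctx_p):
        rep = qc.reciprocity_matrix(ctx_p, ctx_p)
        assert rep.matrix == pytest.approx(np.eye(2), abs=1e-12)

    def test_random_3d_doubly_stochastic(self):
        m = qc.random_model(3, 2, seed=99)
        rep = m.reciprocity("C1", "C2")
        assert rep.max_sum_deviation <= 1e-9


class TestCompatibility:
    def test_worked_example_contexts_incompatible(self, example):
        rep = example.compatibility("P", "E")
        assert not rep.compatible
        assert rep.max_projector_commutator_norm > 1e-3
        assert rep.max_order_effect > 0.1

    def test_context_with_itself_compatible(self, example):
        rep = example.compatibility("P", "P")
        assert rep.compatible
        assert rep.max_projector_commutator_norm <= 1e-9
        assert rep.max_order_effect == pytest.approx(0.0, abs=1e-12)

    def test_unrotated_context_compatible_with_reference(self, example, ctx_p):
        zero = qc.rotation_context_2d(0.0)
        rep = qc.compatibility_report(ctx_p, zero)
        assert rep.compatible

    def test_dimension_mismatch(self, ctx_p):
        with pytest.raises(qc.IncompatibleModelError):
            qc.compatibility_report(ctx_p, qc.canonical_context("Q", 3))


class TestInterference:
    def test_worked_example_violates_total_probability(self, example):
        rep = example.interference("E", "P:P1")
        assert rep.direct_probability == pytest.approx(0.0515, abs=1e-3)
        assert rep.mediated_probabilities == pytest.approx((0.1153, 0.3209),
                                                           abs=1e-3)
        assert rep.classical_sum == pytest.approx(0.4362, abs=1e-3)
        assert rep.interference_term == pytest.approx(-0.3848, abs=1e-3)
        assert rep.classical_sum == pytest.approx(sum(rep.mediated_probabilities),
                                                  abs=1e-12)

    def test_direct_smaller_than_single_mediated_path(self, example):
        """The headline quantum violation: the direct outcome is less likely
        than one specific two-step path to the same outcome."""
        rep = example.interference("E", "P:P1")
        assert rep.direct_probability < rep.mediated_probabilities[1]

    def test_amplitude_completeness_identity(self, example):
        rep = example.interference("E", "P:P1")
        assert rep.amplitude_identity_ok
        assert rep.mediated_amplitude_sum == pytest.approx(0.2269, abs=1e-3)

    def test_compatible_contexts_no_interference(self):
        m = qc.random_model(3, 1, seed=5)
        ctx = m.context("C1")
        twin = qc.build_context("T", ctx.basis * np.array([[1.0], [-1.0], [1.0]]))
        rep = qc.total_probability_decomposition(m.state, twin,
                                                 qc.event(ctx, 0), m.state_context)
        assert rep.interference_term == pytest.approx(0.0, abs=1e-9)


class TestBayesLimit:
    def test_union_conditioning_is_classical(self):
        """Within one context, collapse-then-measure renormalizes the ray
        probabilities exactly as Bayes' rule prescribes."""
        m = qc.random_model(3, 1, seed=11)
        ctx = m.context("C1")
        rep = m.bayes_check("C1", outcomes=(0, 1))
        assert rep.consistent
        p0 = qc.born_probability(m.state, qc.event(ctx, 0), ctx)
        p_u = qc.born_probability(m.state, qc.event(ctx, (0, 1)), ctx)
        assert rep.conditional[0] == pytest.approx(p0 / p_u, abs=1e-12)
        assert rep.conditional[2] == pytest.approx(0.0, abs=1e-12)

    def test_full_union_leaves_distribution_unchanged(self, example):
        rep = example.bayes_check("P")
        probs = example.probability_table("P")["probability"].to_numpy()
        assert rep.conditional == pytest.approx(probs, abs=1e-12)

    def test_single_ray_conditioning_is_certain(self, example):
        rep = example.bayes_check("E", outcomes=(1,))
        assert rep.conditional[1] == pytest.approx(1.0, abs=1e-12)
        assert rep.conditional[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_probability_union_rejected(self, ctx_p):
        s = qc.pure_state((1.0, 0.0), "P")
        with pytest.raises(qc.ImpossibleOutcomeError):
            qc.bayes_equivalence_check(s, ctx_p, outcomes=(1,))


def test_cosine_squared_law_on_rotation_grid():
    """2-D closed form: state at angle α, context rotated by θ →
    P(first outcome) = cos²(α − θ)."""
    for alpha in np.linspace(0.0, 2 * np.pi, 13):
        s = qc.pure_state((np.cos(alpha), np.sin(alpha)), "R0")
        ref = qc.canonical_context("R0", 2)
        for theta in np.linspace(0.0, np.pi, 9):
            ctx = qc.rotation_context_2d(theta)
            p = qc.born_probability(s, qc.event(ctx, 0), ref)
            assert p == pytest.approx(np.cos(alpha - theta) ** 2, abs=1e-12)
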