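# quantumcog

A quantum-probability engine for cognitive models in which top-down
**predictions** and bottom-up **evidence** are complementary measurement
contexts over one shared state space.

Classical (Bayesian) models of the predictive brain place predictions and
sensory evidence in a single sample space, so conditioning is order-free and
the law of total probability holds. Quantum-cognition models drop that
assumption: the cognitive state is a unit vector |S⟩ in an N-dimensional
Hilbert space, and each way of interrogating it — a *measurement context* —
is an ordered orthonormal basis {|C₁⟩,…,|C_N⟩}. The **Born rule** gives the
probability of an outcome event as the squared length of the projection of
|S⟩ onto the event's subspace, P(Cᵢ) = |⟨Cᵢ|S⟩|², and registering an outcome
**collapses** the state (Lüders rule: project, then renormalize). When two
contexts' ray projectors do not commute, sequential outcome probabilities
depend on measurement order (**order effects**) and direct probabilities
differ from their decomposition through an intermediate context
(**interference**, a violation of total probability). When the projectors do
commute, everything here reduces exactly to classical Bayesian conditioning.

`quantumcog` is for researchers in quantum cognition and computational
cognitive science who want these quantities computed, cross-checked and
serialized rather than derived by hand. It provides:

- pure states with named coordinate frames, events (rays and unions),
  Born probabilities, transition amplitudes, collapse, seeded sampling;
- measurement contexts, unitary transition matrices between frames,
  coordinate changes, ray-equivalence tests;
- sequential path probabilities (iterated Born + collapse), signed order
  effects, reciprocity / doubly-stochastic transition-probability matrices,
  projector-commutator compatibility diagnostics, total-probability
  decompositions with interference terms, and a Bayesian-limit check;
- a model container with JSON/YAML round-tripping, a packaged 2-D
  prediction/evidence worked example, a seeded synthetic model generator,
  and a `quantumcog` command-line tool.

## Worked example

The packaged model is 2-dimensional. The prediction context `P` is the
reference frame (canonical basis, outcomes P1/P2); the evidence context `E`
has basis vectors (−0.4372, 0.8994) and (0.8994, 0.4372) in the P frame; the
state is |S⟩ = 0.2269·|P1⟩ + 0.9739·|P2⟩.

```python
>>> import quantumcog as qc
>>> m = qc.example_model()
>>> round(m.born_probability("P:P1"), 4)       # |⟨P1|S⟩|²
0.0515
>>> m.state_in("E").coords.round(4)            # same state, evidence frame
array([0.7767, 0.6299])
>>> m.path("E:E2,P:P1").path_probability       # S → E2 → P1
0.32089089577065144
```

The same numbers from the shell:

```text
$ quantumcog prob --model example
context outcome  probability
      P      P1       0.0515
      P      P2       0.9485
      E      E1       0.6033
      E      E2       0.3967
```

P(P1) ≈ 0.0515 is the probability the top-down system commits to prediction
P1 when interrogated directly. The two-step path through the evidence
outcome E2 is far *more* probable than that direct outcome —
0.3967 × 0.8089 ≈ 0.3209 > 0.0515 — which a classical model cannot produce:

```text
$ quantumcog interference --model example --via E --final P:P1
final_event: P:P1
intermediate_context: E
direct: 0.0515
mediated: [0.1153, 0.3209]
classical_sum: 0.4362
interference: -0.3847
direct_amplitude: 0.2269
mediated_amplitude_sum: 0.2269
amplitude_identity_ok: True
```

The interference term −0.3847 is the gap between the direct probability and
its classical total-probability decomposition through E; the amplitude lines
show that the *amplitudes* still add up exactly — only the probabilities
fail to. Other subcommands: `fixture`, `validate`, `collapse`, `path`,
`order`, `compat`, `sample`, `random` (see `quantumcog --help`). Note that a
path probability is always the **product** of its per-step conditional
probabilities; the `path` command prints the step sum alongside precisely so
the two cannot be confused.

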