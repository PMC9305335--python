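# Methods

## Model

The engine implements projective quantum probability over a finite
N-dimensional real or complex Hilbert space.

- **State.** A pure state is a unit vector; its coordinates are always
  tagged with the frame (measurement context) they are written in. Mixed
  states / density matrices and POVMs are out of scope.
- **Contexts.** A measurement context is an *ordered* orthonormal basis
  with one labelled outcome per basis vector. Exactly one context per model
  is the reference frame and must carry the canonical basis; every other
  basis is stored as coordinate rows in that frame. Orthogonal bases with
  determinant −1 are accepted (the packaged example's change of basis is a
  reflection); probabilities are blind to the determinant and to any global
  phase or sign of a basis vector.
- **Events.** An event is a nonempty set of outcome indices of one context:
  a single index is a ray, several span a union subspace, the full set is
  the sure event. Born probability is the squared projection length; for a
  union it equals the sum over its rays (orthogonality).
- **Collapse.** Lüders rule: project onto the event subspace, divide by the
  projection length. Collapse onto an event of probability ≤ 1e−12 raises
  an error rather than returning a noise direction.
- **Sequential paths.** A path probability is computed by iterating
  Born rule + collapse, each step conditional on the previous outcomes, and
  multiplying. For rank-1 steps this provably equals the product of squared
  transition amplitudes, and the suite asserts that equivalence against an
  independent amplitude-product oracle on 200 seeded models. The sum of the
  per-step probabilities is exposed (and printed by the CLI) only to make a
  common hand-calculation slip — adding the steps instead of multiplying —
  immediately visible; it is never treated as a probability.
- **Union steps in paths** are allowed via project-and-renormalize and
  flagged `coarse`: the elementary theory concerns ray paths, and the flag
  marks the standard projective generalization.
- **Compatibility.** Two contexts are compatible iff every pairwise
  commutator of their ray projectors vanishes (entrywise magnitude ≤ 1e−9).
  For compatible pairs order effects and interference terms vanish
  identically and collapse-then-measure is classical conditioning
  (`bayes_equivalence_check` verifies P(j|U) = P(j)/P(U)); this is the
  Bayesian special case of the framework.

## Parameters and tolerances

| quantity | default | rationale |
|---|---|---|
| state-norm / Gram validation tolerance | 1e−6 | far above float64 noise, far below any modelling signal |
| renormalization window | 1e−3 | amplitudes printed to 4 decimals mis-normalize by ~3e−5; vectors inside the window are rescaled (logged), beyond it construction fails |
| collapse impossibility threshold | 1e−12 | below this the post-measurement direction is numerical noise |
| commutator / compatibility tolerance | 1e−9 | separates exact commutation from generic non-commutation by many orders of magnitude |
| CLI text precision | 4 decimals | matches the worked example; `--json` is full precision |

Renormalization rescales vectors only — directions are never repaired, so a
genuinely non-orthogonal basis is rejected, not silently re-orthogonalized
(which would move the packaged example's printed values).

After a ray collapse the outcome amplitude is made real and nonnegative;
after a union collapse the largest-magnitude amplitude (lowest index on
ties) is made real and nonnegative. This is a pure representation convention — probabilities are
phase-invariant — chosen so repeated collapse is bitwise idempotent.

## Packaged example

The shipped 2-D model stores the worked example's amplitudes exactly as
printed to 4 decimals — state (0.2269, 0.9739) in the prediction frame,
evidence basis rows (−0.4372, 0.8994) and (0.8994, 0.4372) — and
renormalizes them on construction. Printed-value fidelity was preferred over
extra precision; consequently all 4-decimal checks in the tests carry a
±0.001 tolerance, which also absorbs the source material's inconsistent
truncation of such values (one occurrence of the 0.7767 amplitude is
printed as 0.7766; the engine reproduces 0.7767).

## Synthetic generator

`random_model(dimension, n_contexts, seed)` emulates nothing empirical: it
produces structurally valid models for property testing. Contexts are
orthonormalized by QR factorization of standard-normal matrices with the
sign convention (nonnegative R diagonal) that makes the factorization — and
hence the model for a fixed seed — unique across platforms; the state is a
random unit vector in the canonical reference frame (context `C1`, always
included; `n_contexts` counts it). Generated models exercise every engine
invariant (completeness, unitarity, double stochasticity, oracle
equivalence) but say nothing about real behavioral data: no generator here
produces questionnaire responses, noise, or empirical order-effect
magnitudes, so green property tests certify the mathematics, not the
psychology.

`rotation_context_2d(theta)` gives the one-parameter family of rotated 2-D
contexts for which the closed form P(first outcome) = cos²(α − θ) is known;
the suite checks the engine against it on an (α, θ) grid to 1e−12.

## Design choices

- Ordered contexts: permuting basis vectors relabels outcomes, so permuted
  contexts are *not* ray-equivalent; equivalence requires per-index equality
  up to a unit phase. Order effects are defined per labelled outcome.
- The reciprocity report asserts two logically distinct symmetries
  separately: per-ray-pair reciprocity |⟨a|b⟩|² = |⟨b|a⟩|², and double
  stochasticity of the squared-magnitude matrix (a consequence of
  unitarity). In 2-D double stochasticity yields the cross-outcome equality
  |⟨E2|P1⟩|² = |⟨E1|P2⟩|²; neither symmetry extends to union events.
- Order effects for union events use collapse-based sequential
  probabilities, the only definition consistent with coarse projections.
- `PureState` is a dumb container and `pure_state()` the checked
  constructor, so out-of-norm vectors can be represented and *reported on*
  by `validate_state` without being usable in measurements (operations
  re-validate).
- Problem sizes: property suites run at dimensions 2–5 with tens to two
  hundred seeded models; every quantity here is closed-form or a product of
  a handful of inner products, so the whole suite completes in seconds.

## Known limitations

Finite dimensions only; no density matrices, POVMs, or overcomplete frames;
no contextuality analysis (e.g. contextuality-by-default) and no fitting of
contexts or states to behavioral data — the engine computes the forward
probabilities of a specified model.
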