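"""Exception hierarchy.

All domain errors derive from :class:`QuantumCognitionError`, so callers (and
the CLI) can distinguish a modelling problem (exit code 1) from a usage
problem (exit code 2) or a genuine bug.
"""


class QuantumCognitionError(Exception):
    """Base class for all domain errors raised by this package."""


class MalformedStateError(QuantumCognitionError):
    """A state vector is empty, has the wrong length, or is not normalizable."""


class InvalidContextError(QuantumCognitionError):
    """A measurement context's basis is not orthonormal (or is malformed)."""


class IncompatibleModelError(QuantumCognitionError):
    """Objects from different spaces/frames were combined (dimension or
    frame mismatch, or a missing frame context)."""


class ImpossibleOutcomeError(QuantumCognitionError):
    """Collapse was requested onto an event of (numerically) zero probability."""


class InvalidModelError(QuantumCognitionError):
    """A model violates a structural invariant (reference frame, dimensions...)."""


class ModelParseError(InvalidModelError):
    """A model file does not match the expected schema; the message names the
    offending field."""
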