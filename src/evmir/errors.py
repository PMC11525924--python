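"""Exception hierarchy for the pipeline.

All input-validation failures derive from :class:`EvmirError` so callers
(CLI, pipeline driver) can distinguish user errors from bugs.
"""


class EvmirError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(EvmirError, ValueError):
    """A simulation or fit configuration violates its invariants."""


class InvalidInputError(EvmirError, ValueError):
    """A function argument is out of its documented domain."""


class ShapeError(EvmirError, ValueError):
    """Array/matrix dimensions do not match."""


class StateError(EvmirError, ValueError):
    """An intensity matrix is in the wrong processing state for an operation."""


class DegenerateSampleError(EvmirError, ValueError):
    """A sample has no detected positive values and cannot be normalized."""


class DegenerateLabelError(EvmirError, ValueError):
    """Both classes are required but only one is present."""


class StratificationError(EvmirError, ValueError):
    """Stratified cross-validation folds cannot be formed."""


class MissingFeatureError(EvmirError, KeyError):
    """A feature required by a fitted model is absent from the input."""


class ConvergenceError(EvmirError, RuntimeError):
    """The solver failed to converge; carries the last objective value."""

    def __init__(self, message: str, objective: float):
        super().__init__(message)
        self.objective = objective


class NamespaceError(EvmirError, ValueError):
    """A gene id falls outside the declared background universe."""


class VocabularyError(EvmirError, ValueError):
    """A label or stage token is not in the accepted vocabulary."""


class JoinError(EvmirError, ValueError):
    """Sample ids in the metadata and intensity tables do not match."""


class FormatError(EvmirError, ValueError):
    """A file violates its format contract (duplicates, ragged rows...)."""


class ProtocolError(EvmirError, ValueError):
    """An evaluation protocol precondition is not met (e.g. no stage-I subjects)."""
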