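"""Exception and warning types shared across the package."""


class MetanetError(Exception):
    """Base class for all package-specific errors."""


class AbundanceError(MetanetError, ValueError):
    """An abundance table violates the matrix contract (labels, signs, shape)."""


class ParameterError(MetanetError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyResultError(MetanetError, ValueError):
    """An operation produced an empty result where the contract forbids one."""


class EstimationWarning(UserWarning):
    """A statistical estimate is low-confidence (e.g. sparse joint support)."""
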