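"""Exception hierarchy for the generalized modeling toolkit."""


class GenmodError(Exception):
    """Base class for all toolkit errors."""


class NamingError(GenmodError):
    """Duplicate or unknown identifier."""


class StructuralError(GenmodError):
    """Model structure is malformed (dangling reference, missing process, ...)."""


class ConstraintError(GenmodError):
    """Constraint set is inconsistent (cycle, unresolvable reference, ...)."""


class ConfigurationError(GenmodError):
    """Analysis configuration is incomplete or inconsistent."""


class NumericError(GenmodError):
    """A numeric computation could not be carried out (singular matrix,
    non-finite values, non-log-differentiable inner form, ...)."""


class RangeError(GenmodError):
    """A requested value lies outside the admissible range."""


class IntegrityError(GenmodError):
    """A realized model fails its self-consistency checks."""
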