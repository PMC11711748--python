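"""Exception hierarchy shared across the package."""


class BeltQuestError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(BeltQuestError, ValueError):
    """A configuration or model parameter violates its invariant."""


class InputError(BeltQuestError, ValueError):
    """A runtime input (intensity, interval, ...) is invalid."""


class ProtocolError(BeltQuestError, ValueError):
    """The session protocol is infeasible (ramp check, empty block, ...)."""


class GapError(BeltQuestError, ValueError):
    """A missing-data gap cannot be interpolated (edge gap or too long)."""


class ParseError(BeltQuestError, ValueError):
    """A CSV trial log or trace file is malformed."""


class DomainError(BeltQuestError, ValueError):
    """A statistic is requested outside its mathematical domain."""


class DegenerateDataError(BeltQuestError, ValueError):
    """Data without variance (or too few points) for the requested statistic."""


class StructureError(BeltQuestError, ValueError):
    """A study table does not have the expected block structure."""


class NumericError(BeltQuestError, ArithmeticError):
    """Numerical integration failed to converge."""
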