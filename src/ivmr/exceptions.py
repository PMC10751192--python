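"""Exception hierarchy for ivmr."""


class IvmrError(Exception):
    """Base class for all ivmr errors."""


class ConfigurationError(IvmrError):
    """A configuration problem: unresolvable columns, unknown keys, bad schema."""


class InputDataError(IvmrError, ValueError):
    """Input data violate a precondition (empty, degenerate, inconsistent)."""


class CollinearityError(InputDataError):
    """A design matrix is rank deficient (e.g. identical instrument strengths)."""
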