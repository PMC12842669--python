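"""Exception hierarchy shared across radnorm modules."""


class RadnormError(Exception):
    """Base class for all radnorm errors."""


class InputError(RadnormError):
    """Unreadable, malformed or out-of-contract external input (file, CSV)."""


class ContractError(RadnormError):
    """A caller violated an API precondition (wrong depth, bad spec, ...)."""


class DegenerateInputError(RadnormError):
    """Numerically degenerate input (all-zero profile, zero variance, ...)."""
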