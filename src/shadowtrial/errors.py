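"""Exception hierarchy for shadowtrial."""


class ShadowTrialError(Exception):
    """Base class for all shadowtrial errors."""


class FormatError(ShadowTrialError, ValueError):
    """A file does not have the expected structure (e.g. missing columns)."""


class DataError(ShadowTrialError, ValueError):
    """The data violate an invariant (e.g. non-monotonic timestamps)."""


class ParameterError(ShadowTrialError, ValueError):
    """A parameter is outside its valid range."""
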