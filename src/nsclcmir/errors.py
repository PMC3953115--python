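"""Exception types shared across the pipeline."""


class NsclcmirError(Exception):
    """Base class for package-specific errors."""


class ParseError(NsclcmirError, ValueError):
    """A tabular input file violates its dialect (duplicates, bad cells...)."""


class ConfigurationError(NsclcmirError, ValueError):
    """A design/truth/config object is internally inconsistent."""


class UndefinedStatisticError(NsclcmirError, ValueError):
    """A statistic is undefined for the given input (zero variance, n too small)."""
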