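"""Package-specific exception types."""


class ConfigError(ValueError):
    """A configuration value is invalid or inconsistent (unknown marker,
    fraction out of range, joint prevalence exceeding a marginal, ...)."""


class SizingError(ValueError):
    """The requested image canvas cannot contain the tissue core."""


class EmptyROIError(RuntimeError):
    """No pixel above threshold: the core has no detectable tissue and must be
    flagged and excluded downstream."""


class DegenerateTestError(RuntimeError):
    """A statistical test cannot be formed (no events, one-class outcome,
    zero-variance input)."""
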