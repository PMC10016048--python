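"""Exception types shared across the pipeline stages."""


class InvalidConfigError(ValueError):
    """A configuration value is missing, out of range, or inconsistent."""


class TooShortError(ValueError):
    """An input series is too short for the requested operation."""


class OrderingError(ValueError):
    """Trial records are not ordered as the scoring rules require."""


class EmptySampleError(ValueError):
    """An operation that needs at least one observation received none."""


class DegenerateSetError(ValueError):
    """Every element of a set was rejected, or its dispersion is zero."""


class UnknownChannelError(KeyError):
    """A referenced electrode label is not present in the montage."""
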