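"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An input parameter violates its domain (sign, range, emptiness)."""


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class AgeRangeError(ValueError):
    """An age (or age + horizon) falls outside the life table's range."""


class ConsistencyError(ValueError):
    """Two objects that must share a configuration do not."""
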