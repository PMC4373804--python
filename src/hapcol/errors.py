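"""Exception hierarchy shared across the package."""


class HapcolError(Exception):
    """Base class for all package-specific errors."""


class InputError(HapcolError, ValueError):
    """Malformed or inconsistent user input."""


class AlignmentError(InputError):
    """Sequences that do not form a valid alignment (e.g. unequal lengths)."""


class EmptyResultError(InputError):
    """An operation whose filters removed every record."""


class UnsupportedOperationError(HapcolError):
    """Operation requires information the object does not carry
    (e.g. network construction on a sequence-free haplotype table)."""


class UndefinedRatioError(InputError):
    """Ratio with a zero denominator (no potential colonization events)."""
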