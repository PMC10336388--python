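"""Exception types raised across the package."""

__all__ = ["FormatError", "DataError", "CoverageError", "NoDilemmaError"]


class FormatError(ValueError):
    """An input file does not have the required columns or layout."""


class DataError(ValueError):
    """Structurally valid input violates a data invariant (e.g. duplicated
    fish/frame pairs, non-monotone frames)."""


class CoverageError(ValueError):
    """A recording is too short to cover a required analysis window."""


class NoDilemmaError(ValueError):
    """Game payoffs admit no dilemma (volunteering cost >= benefit)."""
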