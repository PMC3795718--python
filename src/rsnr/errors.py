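"""Exception types shared across the package."""


class RSNRError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RSNRError, ValueError):
    """A file does not conform to the expected text format."""


class ConsistencyError(RSNRError, ValueError):
    """Inputs are individually well-formed but mutually inconsistent,
    or an invariant of a domain object is violated."""


class UndefinedScoreError(RSNRError, ValueError):
    """A score cannot be computed for the given design, e.g. the rSNR
    negative set is empty because every other condition shares an
    experimental factor with the target."""
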