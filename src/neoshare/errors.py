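"""Exception hierarchy shared across the pipeline."""


class NeoshareError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeoshareError):
    """A file violates its column or record contract (e.g. missing column)."""


class RowError(FormatError):
    """A single row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(NeoshareError, ValueError):
    """An argument is outside its mathematical domain."""


class HgvsParseError(NeoshareError, ValueError):
    """HGVS.p text outside the supported subset; carries the original text."""

    def __init__(self, text: str, reason: str = "unsupported syntax"):
        self.text = text
        super().__init__(f"cannot parse protein change {text!r}: {reason}")


class ReferenceMismatchError(NeoshareError):
    """The reference residues of a change disagree with the protein sequence."""

    def __init__(self, position: int, expected: str, observed: str):
        self.position = position
        self.expected = expected
        self.observed = observed
        super().__init__(
            f"reference mismatch at residue {position}: "
            f"change expects {expected!r}, sequence has {observed!r}"
        )


class NonEnumerableError(NeoshareError):
    """The change kind does not support peptide enumeration.

    Frameshift and stop-gain events are excluded from neoepitope
    enumeration because the downstream protein product is unreliable
    (premature termination and nonsense-mediated decay).
    """
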