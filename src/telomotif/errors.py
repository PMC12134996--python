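"""Exception hierarchy for telomotif."""


class TelomotifError(Exception):
    """Base class for all telomotif errors."""


class SequenceParseError(TelomotifError):
    """A FASTA/FASTQ record could not be parsed; names the record ordinal."""


class TableFormatError(TelomotifError):
    """A repeat table row violates the tabular dialect; names the row numbers."""


class NoEligibleReadsError(TelomotifError):
    """No read satisfies the minimum-length requirement for a window size."""

    def __init__(self, window: int, what: str = "2t"):
        self.window = window
        super().__init__(
            f"no eligible reads: every read is shorter than {2 * window} bp "
            f"({what} with window {window})"
        )


class GeometryError(TelomotifError):
    """A simulation layout does not fit inside a read."""
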