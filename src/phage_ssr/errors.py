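"""Exception hierarchy shared across the pipeline."""


class PhageSSRError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PhageSSRError):
    """A file does not conform to the expected format (FASTA, GenBank, table)."""


class ComputationError(PhageSSRError):
    """A statistic is undefined for the given inputs (e.g. zero denominator)."""


class GenerationError(PhageSSRError):
    """The synthetic-data generator cannot satisfy the requested constraints."""
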