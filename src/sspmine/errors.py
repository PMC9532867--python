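"""Exception hierarchy for sspmine."""


class SspmineError(Exception):
    """Base class for all package-specific errors."""


class HeaderParseError(SspmineError):
    """A FASTA header did not match the configured dialect."""


class TableParseError(SspmineError):
    """A tabular input (predictor output, TPM matrix, locus table) is malformed."""


class RegistryValidationError(SspmineError):
    """The family registry file violates its contract."""


class SequenceTooShortError(SspmineError):
    """A sequence is too short for the requested prediction (distinct from a negative call)."""


class DegenerateCleavageError(SspmineError):
    """Signal-peptide cleavage at or beyond the C-terminus leaves no mature peptide."""


class MissingPredictionError(SspmineError):
    """An external predictor map lacks a call for a record present in the input."""


class LocusValidationError(SspmineError):
    """A gene locus lies outside its chromosome."""
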