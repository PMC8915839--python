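"""Exception hierarchy shared across the pipeline stages."""


class MedipChipError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MedipChipError, ValueError):
    """A value violates a stage's input contract (negative intensity, bad count, ...)."""


class SchemaError(MedipChipError, ValueError):
    """A tabular input is missing required columns or has an unusable layout."""


class LocusParseError(MedipChipError, ValueError):
    """A locus string could not be parsed; the message names the offending field."""


class ConsistencyError(MedipChipError, ValueError):
    """Records that must agree do not (e.g. one gene's probes on two chromosomes)."""


class UndefinedEnrichmentError(MedipChipError, ZeroDivisionError):
    """Enrichment factor undefined because a denominator margin (n or Nf) is zero."""
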