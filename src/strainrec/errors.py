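"""Exception hierarchy shared across the package."""


class StrainRecError(Exception):
    """Base class for all strainrec-specific errors."""


class FormatError(StrainRecError):
    """An input file could not be parsed in the declared dialect."""


class EmptyInputError(StrainRecError):
    """A file parsed cleanly but contained zero usable records."""


class UnknownSampleError(StrainRecError, KeyError):
    """A sample/strain identifier is absent from a genotype or score table."""


class NoCisVariantError(StrainRecError):
    """No usable cis candidate variant exists for a gene; the gene is dropped."""


class EmptyResourceError(StrainRecError):
    """An expression resource or model list is empty."""


class EmptyTranslationError(StrainRecError):
    """Every entry of a gene set was lost during ortholog translation."""


class SignatureTooSmallError(StrainRecError):
    """Fewer than the minimum number of genes survived harmonization."""


class DegenerateSignatureError(StrainRecError):
    """All signature scores are identical; rank correlation is undefined."""


class AlignmentError(StrainRecError):
    """Gene identifiers or vector lengths do not line up as required."""


class UndefinedCorrelationError(StrainRecError):
    """One side of a correlation has zero rank variance."""


class InfeasibleNullError(StrainRecError):
    """The resource has fewer genes than the signature requires for null draws."""


class UndefinedSensitivityError(StrainRecError):
    """A disease has no scored (non-abstained) comparisons."""


class EmptySummaryError(StrainRecError):
    """No disease summaries were supplied to aggregate."""
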