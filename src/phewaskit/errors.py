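"""Exception types shared across the pipeline stages."""


class PhewaskitError(Exception):
    """Base class for all package errors."""


class ConfigError(PhewaskitError):
    """Invalid simulation or pipeline configuration."""


class ParseError(PhewaskitError):
    """Malformed input record (ICD-9 code, BED line, catalog row, ...)."""


class UnknownReferenceError(PhewaskitError):
    """A planted effect references a SNP or diagnosis code that does not exist."""


class AlignmentError(PhewaskitError):
    """Person identifiers do not line up between two inputs."""


class SingleClassError(PhewaskitError):
    """Outcome vector has only one class; the fit is skipped."""


class RankDeficiencyError(PhewaskitError):
    """Design matrix is rank deficient (collinear covariates)."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design matrix; offending columns: {self.columns}")


class AlleleMismatchError(PhewaskitError):
    """Allele sets at the two sites are incompatible even after strand handling."""


class AmbiguousAllelesError(PhewaskitError):
    """Strand-ambiguous SNP (A/T or C/G); cross-site harmonization is unresolvable."""


class QcError(PhewaskitError):
    """QC removed every SNP or every sample."""

    def __init__(self, message, report=None):
        self.report = report
        super().__init__(message)
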