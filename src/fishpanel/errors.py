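"""Exception hierarchy for the fishpanel pipeline."""


class FishPanelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FishPanelError):
    """Invalid simulation or run configuration; message names the offending field."""


class ValidationError(FishPanelError):
    """Out-of-range or inconsistent input values."""


class UndefinedRatioError(FishPanelError):
    """Probe/control ratio undefined (control mean signal count is zero)."""


class NotApplicableError(FishPanelError):
    """Requested parameter is not defined for this probe class."""


class UndefinedCorrelationError(FishPanelError):
    """Pearson correlation undefined (zero variance in one of the inputs)."""


class RankDeficiencyError(FishPanelError):
    """Logistic design matrix is rank deficient; message names collinear terms."""

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "design matrix is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )


class EnumerationQCError(FishPanelError):
    """All specimens failed enumeration quality control."""

    def __init__(self, failures):
        self.failures = failures
        super().__init__(
            f"all {len(failures)} specimens failed enumeration QC: {failures}"
        )


class PipelineError(FishPanelError):
    """A pipeline stage failed; message names the stage and offending item."""
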