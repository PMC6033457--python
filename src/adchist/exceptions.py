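"""Exception hierarchy shared across the package."""


class AdchistError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AdchistError, ValueError):
    """A configuration object or argument set is internally inconsistent."""


class MissingBValueError(ConfigurationError):
    """A requested b-value has no signal volume in the DWI set."""


class DegenerateROIError(AdchistError, ValueError):
    """An ROI yields no usable ADC values after masking and validity filtering."""


class UndefinedMomentsError(AdchistError, ValueError):
    """Skewness/kurtosis are undefined (constant vector, sigma = 0)."""


class DegenerateVarianceError(AdchistError, ValueError):
    """A two-group test cannot be formed because both variances vanish."""


class CapacityError(AdchistError, ValueError):
    """Exact enumeration would exceed the configured table budget."""


class InsufficientEventsError(AdchistError, ValueError):
    """Too few events to fit a survival model."""


class EmptyCohortError(AdchistError, ValueError):
    """A cohort table contains no patient rows."""


class SchemaError(AdchistError, ValueError):
    """A cohort CSV does not match the documented column dictionary."""


class PipelineStageError(AdchistError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending id."""

    def __init__(self, stage: str, message: str, patient_id=None):
        self.stage = stage
        self.patient_id = patient_id
        detail = f" (patient {patient_id})" if patient_id is not None else ""
        super().__init__(f"stage '{stage}' failed{detail}: {message}")
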