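"""Exception types shared across the pipeline."""


class PipelineError(Exception):
    """Base class for pipeline failures."""


class ConfigurationError(PipelineError):
    """Invalid configuration (duplicate names, unknown analytes, bad ranges)."""


class InfeasibleCalibrationError(PipelineError):
    """An (effect size, AUROC) pair admits no equal-variance calibration."""


class SamplingError(PipelineError):
    """A sampling request exceeds what the cohort can provide."""


class DataError(PipelineError):
    """Input data violate a contract (e.g. non-positive value before log)."""
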