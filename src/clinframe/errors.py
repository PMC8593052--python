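"""Exception hierarchy for cohort validation and configuration problems."""


class ClinframeError(Exception):
    """Base class for all package-specific errors."""


class CohortSchemaError(ClinframeError):
    """A required column is missing from an input table."""


class CohortValidationError(ClinframeError):
    """Row-level content violates a cohort invariant (unknown parameter,
    non-finite value, out-of-interval timestamp, bad event kind, ...)."""


class ReferentialIntegrityError(ClinframeError):
    """A measurement or event references an admission that does not exist."""


class ConfigurationError(ClinframeError):
    """An invalid configuration object (windows, thresholds, generator)."""
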