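"""Exception hierarchy used across the package."""


class CohortmiError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CohortmiError):
    """Data and metadata disagree (unknown variable, bad type, bad code)."""


class ConsistencyError(CohortmiError):
    """Internal invariant of a cohort violated (e.g. non-absorbing death)."""


class ConfigError(CohortmiError):
    """A configuration value is invalid; the message names the field."""


class RankError(CohortmiError):
    """Design matrix is rank deficient; the message names offending columns."""


class ConvergenceError(CohortmiError):
    """An iterative fit failed to converge and no fallback is available."""
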