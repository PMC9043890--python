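"""Exception hierarchy for cohort/schema validation and simulation config errors."""


class ProvalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProvalError):
    """Schema is malformed, or a table does not match the schema (unknown column etc.)."""


class IntegrityError(ProvalError):
    """Structural violation of a cohort table: duplicate participant-visit rows,
    follow-up without a baseline, anchors recorded at baseline, ..."""


class RangeError(ProvalError):
    """A numeric cell falls outside its permitted range, or is a non-numeric sentinel."""


class ConfigError(ProvalError):
    """Simulation configuration is invalid or targets an infeasible correlation
    structure."""
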