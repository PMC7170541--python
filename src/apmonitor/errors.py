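"""Exception types shared across the pipeline."""


class ApmonitorError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ApmonitorError):
    """A configuration value is invalid; the message names the offending field."""


class BundleValidationError(ApmonitorError):
    """A bundle violates an internal invariant (e.g. a date outside config bounds)."""


class ReferentialIntegrityError(ApmonitorError):
    """A table references a patient_id absent from the patient registry."""

    def __init__(self, table: str, row: int, patient_id: str):
        self.table = table
        self.row = row
        self.patient_id = patient_id
        super().__init__(
            f"unknown patient_id {patient_id!r} in table {table!r} at row {row}"
        )


class SchemaError(ApmonitorError):
    """An input file is missing or does not match its documented schema."""


class MissingInputError(ApmonitorError):
    """A required bundle file is absent."""
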