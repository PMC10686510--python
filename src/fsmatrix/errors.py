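"""Exception hierarchy for the fire-safety matrix pipeline."""


class FsMatrixError(Exception):
    """Base class for all package errors."""


class SchemaError(FsMatrixError):
    """A CSV header does not match the declared schema."""


class ValidationError(FsMatrixError):
    """A record violates a range or type constraint.

    Carries the zero-based data-row index when raised from a reader.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DuplicateRecordError(FsMatrixError):
    """Two records share the same (item, evaluator) key."""


class FixtureIntegrityError(FsMatrixError):
    """A packaged fixture failed its checksum."""
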