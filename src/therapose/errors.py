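"""Exception hierarchy for the pipeline.

Every error raised on bad external input derives from :class:`TheraposeError`
so the CLI can map them to stable exit codes (format/validation problems
exit 3, missing inputs exit 2, everything else 1).
"""


class TheraposeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TheraposeError):
    """A file does not conform to its declared format."""


class ValidationError(TheraposeError):
    """Well-formed input violates a semantic invariant."""


class CalibrationError(TheraposeError):
    """A baseline (sitting height, keyboard white level, first frame) cannot be established."""


class ConfigurationError(TheraposeError):
    """A required configuration entry is missing or inconsistent."""


class PersonLookupError(TheraposeError, LookupError):
    """The requested person id is absent from a keypoint file."""

    def __init__(self, person_id, available):
        self.person_id = person_id
        self.available = sorted(available)
        super().__init__(
            f"person_id {person_id} not found; available ids: {self.available}"
        )
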