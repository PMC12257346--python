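"""Exception hierarchy for beamtune."""


class BeamtuneError(Exception):
    """Base class for all beamtune errors."""


class SchemaError(BeamtuneError):
    """A file is missing required metadata or has an unknown layout."""


class ProfileValidationError(BeamtuneError):
    """Profile data violates an invariant (ordering, length, duplicates)."""


class DegenerateProfileError(BeamtuneError):
    """A profile cannot be normalized (non-positive or absent CAX dose)."""


class MetricUndefinedError(BeamtuneError):
    """A level crossing needed by a metric does not exist on the profile."""


class GeometryError(BeamtuneError):
    """Profiles with inconsistent or incomplete acquisition geometry."""


class CalibrationError(BeamtuneError):
    """Film calibration data is unusable or a dose is out of range."""


class RegistrationError(BeamtuneError):
    """Rigid registration cannot be performed (no overlap, flat image)."""
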