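"""Exception hierarchy.

All package errors derive from :class:`IVMQuantError` so callers can catch
one base class; the subclasses distinguish the failure domain (file
structure, metadata, calibration inputs, run configuration, value checks).
"""


class IVMQuantError(Exception):
    """Base class for all ivmquant errors."""


class StructuralError(IVMQuantError):
    """Image/stack geometry is inconsistent (e.g. frames of differing shape)."""


class MetadataError(IVMQuantError):
    """Session sidecar is missing, short, or inconsistent with the image data."""


class CalibrationError(IVMQuantError):
    """A calibration frame is unusable (nonpositive phantom, zero standard...)."""


class ConfigurationError(IVMQuantError):
    """A required component or configuration entry is missing or contradictory."""


class ValidationError(IVMQuantError):
    """An input value violates a documented precondition."""
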