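"""Exception hierarchy shared across the package."""


class ToothSegError(Exception):
    """Base class for all package errors."""


class FormatError(ToothSegError):
    """Unreadable, empty, or unsupported mesh file."""


class LabelError(ToothSegError):
    """Label sidecar inconsistent with the mesh or the FDI code space."""


class GeometryError(ToothSegError):
    """Degenerate geometry (zero-area face, invalid index)."""


class ParameterError(ToothSegError):
    """An argument outside its documented domain."""


class SimplificationError(ToothSegError):
    """Edge collapse could not reach the requested face count."""


class StateError(ToothSegError):
    """Operation applied in an invalid state (e.g. double normalization)."""


class ShapeError(ToothSegError):
    """Array dimensions inconsistent with the operator's contract."""


class ConfigError(ToothSegError):
    """Inconsistent network or training configuration."""


class DataError(ToothSegError):
    """Dataset-level inconsistency (empty set, length mismatch)."""


class VersionError(ToothSegError):
    """Checkpoint/config mismatch on load."""


class SpecError(ToothSegError):
    """Infeasible synthetic-arch specification."""
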