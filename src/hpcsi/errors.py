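"""Exception hierarchy for the hpcsi pipeline."""


class HpcsiError(Exception):
    """Base class for all hpcsi errors."""


class ValidationError(HpcsiError, ValueError):
    """Invalid user input (non-finite values, negative rates, bad shapes)."""


class CalibrationError(HpcsiError):
    """Volume calibration cannot be performed (e.g. fewer than 2 pairs)."""


class MappingError(HpcsiError):
    """A chamber cannot be mapped onto the voxel grid."""


class CoverageError(HpcsiError):
    """The frame schedule is not covered by the kinetic trajectory."""


class AliasingError(HpcsiError):
    """A resonance falls outside the acquired spectral width."""


class AggregationError(HpcsiError):
    """Voxel aggregation is impossible (empty chamber mapping)."""


class ConfigurationError(HpcsiError):
    """Inconsistent analysis configuration (e.g. overlapping peak windows)."""


class NumericalError(HpcsiError):
    """A numerical routine failed to converge; carries diagnostics."""


class RegistryError(HpcsiError, KeyError):
    """Unknown fixture or registry entry."""
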