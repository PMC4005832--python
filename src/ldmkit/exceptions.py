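"""Exception hierarchy for ldmkit."""


class LdmkitError(Exception):
    """Base class for all ldmkit errors."""


class InvalidCalibrationError(LdmkitError):
    """Calibration parameters are non-positive or otherwise unusable."""


class EmptyInputError(LdmkitError):
    """An operation received an empty frame stack or trace."""


class NoSpotError(LdmkitError):
    """A frame contains no detectable laser spot (empty binarization mask)."""


class OutOfBoundsError(LdmkitError):
    """A spot centroid falls outside the target grid."""


class InsufficientSpotsError(LdmkitError):
    """Fewer than two spots: distance-based indices are undefined."""


class DegenerateConfigurationError(LdmkitError):
    """All spots coincide; nearest-neighbour statistics are undefined."""


class DegenerateRasterError(LdmkitError):
    """Intended pitch exceeds the target extent; no raster fits."""


class MissingPairsError(LdmkitError):
    """Paired comparison requested but some subjects lack a matching session."""
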