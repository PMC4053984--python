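"""Exception hierarchy for assay-quantitation and scanning failures."""


class ZfbindError(ValueError):
    """Base class for all package-specific errors."""


class UnquantifiableLaneError(ZfbindError):
    """Both the shifted and unshifted band densities are zero."""


class DegenerateComparisonError(ZfbindError):
    """Denominator group of a binding-strength ratio has zero mean."""


class InvalidCalibrationError(ZfbindError):
    """Methylation standards are equal; the dot-blot calibration is void."""


class IncompleteRecordError(ZfbindError):
    """A qPCR record lacks a Ct value without being flagged as failed."""


class NoDynamicRangeError(ZfbindError):
    """Scrambled-competitor shifted fraction does not exceed the unmutated one."""


class IncompletePositionError(ZfbindError):
    """A scanned position is missing one or more of its three substitutions."""


class AmbiguousInputError(ZfbindError):
    """Duplicate (position, substituted base) competition records."""


class IncompleteAlignmentError(ZfbindError):
    """A motif offset leaves defined positions outside the site sequence."""


class AlignmentError(ZfbindError):
    """Inconsistent or impossible alignment offsets."""


class SiteNotFoundError(ZfbindError):
    """A reference binding site could not be located in its hotspot region."""


class NonBindingFragmentError(ZfbindError):
    """Truncation mapping was asked to minimize a fragment that never bound."""
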