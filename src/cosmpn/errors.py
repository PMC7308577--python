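"""Exception hierarchy for the COS-MPN pipeline."""


class CosmpnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CosmpnError, ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValidationError):
    """A table file could not be parsed; the message names the offending row."""


class InsufficientDataError(CosmpnError, ValueError):
    """Too few usable observations for the requested fit or estimate."""


class CalibrationError(CosmpnError, ValueError):
    """A calibration (hydrolysis anchors, biomass standards) is infeasible."""


class SelectionError(CosmpnError, ValueError):
    """A dilution-level selection rule cannot be applied (e.g. <3 levels)."""


class AboveRangeError(CosmpnError, ValueError):
    """All tubes positive at every level: the MPN likelihood has no finite maximum."""
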