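"""Exception hierarchy for sedtriad."""


class SedtriadError(Exception):
    """Base class for all sedtriad errors."""


class GuidelineError(SedtriadError):
    """Invalid sediment quality guideline (e.g. non-positive PEL)."""


class EmptyClassError(SedtriadError):
    """No analyte of the requested contaminant class has a guideline value."""


class DegenerateControlError(SedtriadError):
    """Control absorbance is zero or negative; viability cannot be normalized."""


class InconsistentMaximumError(SedtriadError):
    """A %tail value exceeds the declared study-wide maximum effect."""


class PairingError(SedtriadError):
    """Paired conditions (e.g. with/without FPG) do not share the same key."""


class IncompletePanelError(SedtriadError):
    """Biomarker panel is missing a station x biomarker cell required for IBR."""


class SchemaError(SedtriadError):
    """Tabular input violates a declared schema."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])
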