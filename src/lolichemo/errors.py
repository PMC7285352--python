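"""Exception hierarchy for the lolichemo pipeline."""


class LolichemoError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LolichemoError):
    """Input file does not match the expected wide spectral layout."""


class DuplicateSpectrumError(FormatError):
    """Two rows share the same (sample_id, replicate) key."""


class EmptyDatasetError(LolichemoError):
    """A dataset with zero usable samples."""


class DomainError(LolichemoError):
    """A value outside the mathematical domain of an operation."""


class DegenerateSpectrumError(LolichemoError):
    """A spectrum with zero variance where scaling is required."""


class TreatmentCodeError(LolichemoError):
    """Unparseable or inconsistent pre-treatment code."""


class WindowError(LolichemoError):
    """Smoothing/derivative window does not fit on the wavelength grid."""


class RankError(LolichemoError):
    """More components requested than the data can support."""


class GroupingError(LolichemoError):
    """Cross-validation group count incompatible with the sample count."""


class SelectionError(LolichemoError):
    """No successful candidate equation to select from."""
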