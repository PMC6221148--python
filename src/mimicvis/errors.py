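"""Exception hierarchy shared across the package."""


class MimicvisError(Exception):
    """Base class for package errors."""


class RangeError(MimicvisError, ValueError):
    """A wavelength or value outside the supported range."""


class GridMismatchError(MimicvisError, ValueError):
    """Spectra that must share a wavelength grid do not."""


class ConfigurationError(MimicvisError, ValueError):
    """An unknown preset, bad parameter, or invalid configuration."""


class NormalizationError(MimicvisError, ValueError):
    """The normalization reference produced a zero or invalid catch."""


class UnsupportedSystemError(MimicvisError, ValueError):
    """An operation undefined for this visual system (e.g. achromatic
    contrast for a system without a double-cone channel)."""


class DomainError(MimicvisError, ValueError):
    """Inputs outside the mathematical domain of an operation."""


class TranslationError(MimicvisError, ValueError):
    """A nucleotide fragment that cannot be translated cleanly."""


class AlignmentError(MimicvisError, ValueError):
    """The spectral-tuning window could not be located in a sequence."""


class FormatError(MimicvisError, ValueError):
    """A malformed input file."""


class FittingError(MimicvisError, ValueError):
    """A regression or model fit that cannot proceed."""


class InsufficientDataError(MimicvisError, ValueError):
    """Too few observations for the requested statistic."""


class ScenarioError(MimicvisError, ValueError):
    """An invalid synthetic-data scenario."""
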