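"""Exception hierarchy for meatspec."""


class MeatspecError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MeatspecError):
    """A configuration object is internally inconsistent or infeasible."""


class ParseError(MeatspecError):
    """A CSV/config file failed validation; message carries the location."""


class DegenerateSpectrumError(MeatspecError):
    """A spectrum is constant (or otherwise untransformable); names the sample."""


class ScatterFitError(MeatspecError):
    """MSC slope fit collapsed (|b| below tolerance) for a sample."""


class EmptySelectionError(MeatspecError):
    """A wavelength-selection method retained no wavelengths."""


class NoStructureError(MeatspecError):
    """Extrema detection found fewer than two peaks/troughs."""


class SingularDesignError(MeatspecError):
    """A regression design matrix is rank deficient."""


class RankExhaustedError(MeatspecError):
    """PLS component extraction collapsed before the requested count."""
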