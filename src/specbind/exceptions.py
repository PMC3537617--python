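"""Exception hierarchy.

All package errors derive from :class:`SpecbindError` so callers can catch a
single base class; the subclasses distinguish data-format problems from
numerical/fit problems and from pipeline configuration problems.
"""


class SpecbindError(Exception):
    """Base class for all errors raised by specbind."""


class FormatError(SpecbindError):
    """A delimited-text file does not have the expected columns/layout."""


class DataValidationError(SpecbindError):
    """Input data violate a domain invariant (ordering, sign, length)."""


class GridAlignmentError(SpecbindError):
    """Two spectra do not share an identical wavelength grid."""


class InsufficientDataError(SpecbindError):
    """Too few usable points for the requested fit."""


class DegenerateBaselineError(SpecbindError):
    """Baselines too close to define a state fraction."""


class FitConvergenceError(SpecbindError):
    """A nonlinear fit failed to converge or is non-identifiable."""


class ConfigError(SpecbindError):
    """Pipeline configuration is invalid."""


class DependencyError(ConfigError):
    """A pipeline stage is missing an input produced by no earlier stage."""
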