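"""Exception hierarchy.

All coilkit-specific failures derive from :class:`CoilkitError` so callers
(and the CLI) can catch one base class and map it to a nonzero exit code.
"""


class CoilkitError(Exception):
    """Base class for all coilkit errors."""


class ParseError(CoilkitError):
    """A file or text input could not be parsed (names the offending record)."""


class StructureError(CoilkitError):
    """A structure is empty or otherwise unusable."""


class TopologyError(CoilkitError):
    """Ensemble frames do not share an identical atom inventory."""


class SelectionError(CoilkitError):
    """An atom selection resolved to nothing under strict mode, or names
    chains that do not exist."""


class RegisterFormatError(ParseError):
    """A heptad-register specification violates the documented text format."""


class CorrespondenceError(CoilkitError):
    """Point sets passed to a superposition do not correspond."""


class AxisError(CoilkitError):
    """Too few residues to define a helix axis."""


class EmptyAggregateError(CoilkitError):
    """An aggregate (mean over heptads, ...) had no rows after filtering."""


class DegenerateVarianceError(CoilkitError):
    """B-factor normalization is undefined (zero variance or n == N)."""


class UnitError(CoilkitError):
    """Concentration units of model and data disagree."""


class FitError(CoilkitError):
    """A nonlinear fit failed to converge or the data are unidentifiable."""


class ConfigError(CoilkitError):
    """An analysis configuration is invalid or references missing files."""
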