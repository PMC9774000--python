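"""Exception hierarchy.

``StrainrankError`` is the common base so callers can catch everything the
library raises with one except clause; the CLI maps it to a nonzero exit.
"""


class StrainrankError(Exception):
    """Base class for all errors raised by strainrank."""


class FormatError(StrainrankError):
    """A file could not be parsed as the expected external format."""


class DataError(StrainrankError):
    """The file parsed, but its content violates a domain invariant."""


class GeometryError(StrainrankError):
    """Degenerate coordinates (e.g. collinear points in a torsion)."""


class ParameterError(StrainrankError):
    """Infeasible or inconsistent user parameters."""
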