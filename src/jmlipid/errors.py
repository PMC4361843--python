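"""Exception hierarchy for jmlipid.

All package-specific failures derive from :class:`JMLipidError` so callers
can catch one base class at pipeline level while tests target the precise
failure mode.
"""


class JMLipidError(Exception):
    """Base class for all jmlipid errors."""


class InvalidResidueError(JMLipidError):
    """Amino-acid code outside the 20 standard one-letter codes."""


class TruncatedJMError(JMLipidError):
    """Fewer residues follow the TM span than the requested JM length."""


class CompositionError(JMLipidError):
    """Leaflet fractions invalid (negative or not summing to 1)."""


class PackingError(JMLipidError):
    """Box too small to place the requested lipids without overlap."""


class GeometryError(JMLipidError):
    """Protein layout or analysis range incompatible with the box."""


class InstabilityError(JMLipidError):
    """Integrator produced a divergent step; reduce the timestep."""


class UnknownSpeciesError(JMLipidError):
    """Lipid species absent from a trajectory or leaflet specification."""


class EmptyInputError(JMLipidError):
    """Analysis called on zero frames / an empty collection."""


class CalibrationError(JMLipidError):
    """Target first-shell window unreachable over the scanned grid."""


class InsufficientDataError(JMLipidError):
    """Too few records to compute the requested statistic."""


class ReferenceError_(JMLipidError):
    """Annotation refers to a sequence id that was not supplied."""


class ParseError(JMLipidError):
    """Malformed input file; message locates the offending row."""


class ConfigError(JMLipidError):
    """Invalid pipeline configuration."""
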