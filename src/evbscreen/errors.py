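"""Exception hierarchy.

Every anticipated failure mode raises a subclass of :class:`EVBError` so
callers (and the campaign executor, which must never abort on a single bad
task) can distinguish scientific failures from programming errors.
"""

from __future__ import annotations


class EVBError(Exception):
    """Base class for all errors raised by evbscreen."""


class InvalidInputError(EVBError, ValueError):
    """A numeric argument is non-finite or outside its documented domain."""


class MissingFieldError(EVBError, ValueError):
    """A required field (e.g. donor-acceptor distance) is absent."""


class IncompleteSamplingError(EVBError):
    """A mapping window has no (or too few) frames."""

    def __init__(self, message: str, window=None):
        super().__init__(message)
        self.window = window


class InsufficientOverlapError(EVBError):
    """No histogram bin reached the minimum count."""


class NoBarrierError(EVBError):
    """The free-energy profile is monotone: no transition state exists.

    Carries the offending profile for inspection.
    """

    def __init__(self, message: str, profile=None):
        super().__init__(message)
        self.profile = profile


class InvertedRegionError(EVBError, ValueError):
    """Marcus expression undefined: ΔG0 + λ ≤ 0."""


class CalibrationError(EVBError):
    """Calibration did not converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class VariantParseError(EVBError, ValueError):
    """Malformed variant label."""


class InvalidPlanError(EVBError, ValueError):
    """A protocol plan violates its invariants."""


class StructureError(EVBError):
    """Base for structure-level failures."""


class PDBParseError(StructureError, ValueError):
    """Unparseable PDB content."""


class EmptyStructureError(StructureError):
    """No ATOM records found."""


class CannotTruncateError(StructureError):
    """Residue cannot be truncated (missing backbone, or unsupported type)."""


class IdentityError(StructureError):
    """Wild-type identity check failed at a substitution site."""


class UnsupportedSubstitutionError(StructureError):
    """Non Ala/Gly target requested without a rotamer adapter."""


class SelectorError(StructureError):
    """Atom selector matched zero or several atoms."""
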