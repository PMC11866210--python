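"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`AdvibError`
so callers (and the CLI) can distinguish usage errors from genuine bugs.
"""


class AdvibError(Exception):
    """Base class for all package errors."""


class FormatError(AdvibError, ValueError):
    """Malformed input file (inconsistent frames, unparsable header, ...)."""


class ElementError(AdvibError, KeyError):
    """Unknown chemical element symbol."""


class PreconditionError(AdvibError, ValueError):
    """An operation was called on input violating its stated preconditions."""


class EmptyTrajectoryError(PreconditionError):
    """An operation would leave (or received) a trajectory with no frames."""


class MatchingError(AdvibError, RuntimeError):
    """Symmetry partner matching failed (distance above cutoff, no bijection)."""


class TopologyError(AdvibError, ValueError):
    """Molecular topology does not have the expected roles/connectivity."""


class IntegrationError(AdvibError, RuntimeError):
    """MD integration cannot proceed (unstable time step, bad model)."""
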