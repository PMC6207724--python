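"""Exception hierarchy shared across the analysis stages."""


class Shp2KinError(Exception):
    """Base class for all package-specific failures."""


class KeyMismatchError(Shp2KinError):
    """Peaks from different spectra do not share a (residue, atom-group) key."""


class DegenerateAxisError(Shp2KinError):
    """Open and closed reference peaks coincide; no projection axis exists."""


class EmptySelectionError(Shp2KinError):
    """All residues were removed by the filters; nothing left to estimate."""


class InsufficientDataError(Shp2KinError):
    """Fewer data points than the estimator requires."""


class BoundaryError(Shp2KinError):
    """A population exactly at 0 or 1 has no finite equilibrium constant."""


class ParseError(Shp2KinError):
    """A table or config file could not be read; carries file/line context."""

    def __init__(self, message, path=None, line=None):
        ctx = ""
        if path is not None:
            ctx += f" [{path}"
            ctx += f":{line}]" if line is not None else "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


class FitError(Shp2KinError):
    """Nonlinear regression failed to converge; may carry the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class UnidentifiableError(Shp2KinError):
    """The data carry no information about a requested parameter."""


class DataInconsistencyError(Shp2KinError):
    """Fitted values contradict the physical model (e.g. negative on-rate)."""


class SolverError(Shp2KinError):
    """ODE integration or linear steady-state solve failed."""
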