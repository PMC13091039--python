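"""Exception and warning types shared across the package."""


class EnsembleFPError(Exception):
    """Base class for all package errors."""


class ParseError(EnsembleFPError):
    """A file or compact atom-address string could not be parsed."""


class CompositionError(EnsembleFPError):
    """Ensemble members disagree on chain composition or identifiers."""


class DimensionError(EnsembleFPError):
    """A confidence matrix does not match the model it describes."""


class ResolutionError(EnsembleFPError):
    """An atom reference could not be resolved to a unique atom."""


class CoverageError(EnsembleFPError):
    """A residue range is not fully covered by a model or token map."""


class ValidationError(EnsembleFPError):
    """A run configuration or generator spec violates its constraints."""


class DegenerateGeometryWarning(UserWarning):
    """Superposition input was degenerate (coincident/collinear points)."""
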