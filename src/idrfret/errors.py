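"""Exception types shared across the pipeline."""


class IdrFretError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(IdrFretError, ValueError):
    """A generator or analysis parameter violates its invariants."""


class AlphabetError(IdrFretError, ValueError):
    """A protein sequence contains non-standard residues."""


class InsufficientPhotonsError(IdrFretError, ValueError):
    """Too few photons in a decay histogram to fit a lifetime."""


class InsufficientDataError(IdrFretError, ValueError):
    """Too few observations for the requested estimate."""


class FitError(IdrFretError, RuntimeError):
    """An optimiser failed to converge; carries diagnostics in args."""


class DivisionError(IdrFretError, ZeroDivisionError):
    """A denominator channel or band sum is zero."""


class MissingControlError(IdrFretError, ValueError):
    """No wells match the control label used for normalization."""


class NormalizationError(IdrFretError, ValueError):
    """The normalization anchor has zero intensity."""


class DegenerateDesignError(IdrFretError, ValueError):
    """All concentrations identical (or otherwise rank-deficient design)."""


class SpanError(IdrFretError, ValueError):
    """Smoothing span too small to include enough neighbours."""


class DomainError(IdrFretError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class PlacementError(IdrFretError, RuntimeError):
    """Synthetic cells could not be placed without overlap."""


class GeometryError(IdrFretError, ValueError):
    """A chain conformation violates its bonded geometry."""


class UndefinedKappaError(IdrFretError, ValueError):
    """Kappa is undefined for sequences without charged residues."""


class ShapeError(IdrFretError, ValueError):
    """Image / label array shapes do not match."""
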