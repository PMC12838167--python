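"""Exception hierarchy shared across the package."""


class PhageCocktailError(ValueError):
    """Base class for all package-specific errors."""


class MatrixParseError(PhageCocktailError):
    """A susceptibility-matrix file could not be parsed."""


class MatrixValidationError(PhageCocktailError):
    """A susceptibility matrix or catalog violates a structural invariant."""


class BinarizationError(PhageCocktailError):
    """Entries cannot be binarized under the given rule."""


class IncompletePanelError(PhageCocktailError):
    """A knockout-mutant panel is missing required genotypes."""


class InconsistentPanelError(PhageCocktailError):
    """A knockout-mutant panel contradicts the receptor model."""


class IndeterminateDenominatorError(PhageCocktailError):
    """Titration counts cannot yield a CFU denominator (all zero)."""


class InfeasibleSpecError(PhageCocktailError):
    """A marginal specification violates a set-union bound before search."""
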