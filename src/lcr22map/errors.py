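"""Exception taxonomy for the lcr22map pipeline."""


class Lcr22MapError(Exception):
    """Base class for all package errors."""


class StructureError(Lcr22MapError):
    """A homolog's block structure violates its invariants (overlap, ordering, junctions)."""


class HomologyError(Lcr22MapError):
    """Recombination requested between modules of incompatible orientation."""


class BoundsError(Lcr22MapError):
    """An offset or index falls outside the structure it addresses."""


class ParameterError(Lcr22MapError):
    """A simulation or pipeline parameter is out of its valid range."""


class ParseError(Lcr22MapError):
    """A BNX/CMAP/XMAP dialect file could not be parsed.

    Carries the 1-based line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ChainingGapError(Lcr22MapError):
    """No molecule spans an adjacent-copy junction during duplicon chaining."""

    def __init__(self, junction: str):
        self.junction = junction
        super().__init__(f"no spanning molecule supports junction {junction}")


class DataConsistencyError(Lcr22MapError):
    """Input genotype data contradicts the hemizygous-deletion model."""


class InsufficientMarkersError(Lcr22MapError):
    """Fewer informative STRP markers than the required minimum."""


class InconsistentMarkersError(Lcr22MapError):
    """Informative STRP markers disagree on the parent of deletion origin."""


class IrreconcilableDonorsError(Lcr22MapError):
    """No donor pair is consistent with the assigned label sites."""


class ModelInconsistencyError(Lcr22MapError):
    """The recombination product implied by the inferred donors does not match the
    observed deletion-containing haplotype."""
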