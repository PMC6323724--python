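"""Exception hierarchy shared across the package."""


class SeptevoError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SeptevoError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(SeptevoError, ValueError):
    """An input object violates its documented invariants."""


class EmptyFamilyError(SeptevoError):
    """All gene copies of a simulated family were lost; resample."""


class NotASplitError(SeptevoError, ValueError):
    """The requested outgroup does not correspond to a branch of the unrooted tree."""


class MappingError(SeptevoError, ValueError):
    """A gene leaf, taxon or residue could not be mapped to its target."""


class UnresolvedPolytomyError(SeptevoError):
    """A polytomy exceeds the exhaustive-resolution cap."""

    def __init__(self, node_label: str, degree: int, cap: int):
        self.node_label = node_label
        self.degree = degree
        self.cap = cap
        super().__init__(
            f"polytomy at node {node_label!r} has {degree} children, "
            f"exceeding the exhaustive-resolution cap of {cap}"
        )


class NumericalFailureError(SeptevoError, RuntimeError):
    """An optimizer failed to converge after all restarts."""
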