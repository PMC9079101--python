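"""Typed errors raised across the pipeline.

Every error a caller may want to catch and handle distinctly gets its own
class; all inherit from :class:`NetImpactError` so a batch driver can catch
the family and attach provenance (which module, which patient) before
re-raising or logging.
"""


class NetImpactError(Exception):
    """Base class for all package errors."""


class ValidationError(NetImpactError):
    """Input violates a documented precondition or schema rule."""


class DegenerateGraphError(ValidationError):
    """Graph too small (or otherwise degenerate) for centrality."""


class BindingError(ValidationError):
    """Parcellation labels and centrality table do not match."""

    def __init__(self, message, missing_labels=()):
        super().__init__(message)
        self.missing_labels = tuple(missing_labels)


class GridMismatchError(ValidationError):
    """Lesion and parcellation grids differ in shape or spacing."""


class UnscorableLesionError(NetImpactError):
    """Lesion overlaps no region with positive centrality (raw score 0).

    Mirrors the cohort exclusion of infarcts restricted to infratentorial
    regions or isolated white matter: such lesions are outside the grey
    matter network atlas and receive no score.
    """


class FormatError(NetImpactError):
    """File contents violate the expected on-disk format."""


class DegenerateOutcomeError(NetImpactError):
    """Outcome has a single level (all 0 or all 1); no model is fittable."""


class SeparationError(NetImpactError):
    """Complete or quasi-complete separation detected during fitting."""


class ConvergenceError(NetImpactError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class EmptySubsetError(NetImpactError):
    """Model conditioning set selects no rows (e.g. wrong baseline arm)."""
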