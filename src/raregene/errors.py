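"""Exception hierarchy for raregene.

All package-specific errors derive from :class:`RareGeneError` so callers can
catch pipeline failures without masking programming errors.
"""


class RareGeneError(Exception):
    """Base class for all raregene errors."""


class ParameterError(RareGeneError, ValueError):
    """An argument is outside its documented domain."""


class StateError(RareGeneError, RuntimeError):
    """An operation was requested in a state that cannot support it
    (e.g. twin injection with no causal SNPs)."""


class UndefinedScoreError(RareGeneError, ValueError):
    """A gene score is undefined for this gene (e.g. the proportion score
    for a gene with zero rare SNPs).  Callers may skip the gene."""


class UndefinedStatisticError(RareGeneError, ValueError):
    """A summary statistic is undefined on this input (constant vectors,
    empty causal sets, all-zero variance components)."""
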