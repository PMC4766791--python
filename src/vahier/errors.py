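"""Exception hierarchy for vahier."""


class VahierError(Exception):
    """Base class for all package errors."""


class RuleConfigError(VahierError):
    """A rule set or hierarchy config violates the documented schema."""


class UsageError(VahierError):
    """Inputs violate an operation's preconditions (e.g. age-group mismatch)."""


class HierarchyError(VahierError):
    """A fired cause is not mapped by the hierarchy or its fallback list."""


class MappingError(VahierError):
    """A reference cause set matches no harmonization rule."""


class AllocationError(VahierError):
    """A proportional reallocation has no singly-assigned target deaths."""


class ScenarioError(VahierError):
    """No eligible country rows, or an empty cause intersection."""


class ResamplingError(VahierError):
    """A retained cause has an empty death pool."""


class MetricUndefinedError(VahierError):
    """A metric is undefined for the given inputs (degenerate margins)."""


class ModelError(VahierError):
    """A symptom model cannot be built (e.g. unsatisfiable predicate)."""
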