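"""Exception hierarchy for dagforge.

Every error raised by the library derives from :class:`DagforgeError`, so
callers (and the CLI) can distinguish library failures from genuine bugs.
"""


class DagforgeError(Exception):
    """Base class for all dagforge errors."""


class DuplicateNameError(DagforgeError):
    """Two node specs share the same name within one graph."""


class UnresolvedReferenceError(DagforgeError):
    """A node reference names a node that is not declared in the graph."""


class CycleError(DagforgeError):
    """The directed graph contains a cycle (self-loops included).

    The message names one offending cycle, e.g. ``A -> B -> A``.
    """

    def __init__(self, cycle_nodes):
        self.cycle_nodes = list(cycle_nodes)
        path = " -> ".join(self.cycle_nodes + [self.cycle_nodes[0]])
        super().__init__(f"graph contains a directed cycle: {path}")


class KindError(DagforgeError):
    """A node kind is used in an unsupported position (e.g. two selection
    nodes, or a missing node whose mask is itself non-standard)."""


class DomainError(DagforgeError):
    """An argument to a generating function is outside its legal range."""


class ConfigError(DagforgeError):
    """Invalid generator or run configuration."""


class SchemaError(DagforgeError):
    """A YAML simulation document violates the schema.

    ``path`` locates the offending entry, e.g. ``graph.Seq.kwargs``.
    """

    def __init__(self, message, path=None):
        self.path = path
        super().__init__(f"{path}: {message}" if path else message)


class FunctionResolutionError(DagforgeError):
    """A dotted function name could not be resolved to a callable."""


class UnserializableFunctionError(DagforgeError):
    """A node's callable has no recoverable qualified name (lambda/closure)."""


class FunctionEvaluationError(DagforgeError):
    """A user-supplied generating function raised; reports node and sample."""

    def __init__(self, node_name, sample_index, cause):
        self.node_name = node_name
        self.sample_index = sample_index
        super().__init__(
            f"function for node {node_name!r} failed at sample "
            f"{sample_index}: {cause!r}"
        )


class RejectionBudgetExceededError(DagforgeError):
    """Selection rejected too many candidates; acceptance probability is
    (near) zero under the budget."""

    def __init__(self, accepted, attempts):
        self.accepted = accepted
        self.attempts = attempts
        rate = accepted / attempts if attempts else 0.0
        super().__init__(
            f"rejection budget exhausted: {accepted} samples accepted in "
            f"{attempts} attempts (acceptance rate {rate:.2e})"
        )


class LabelError(DagforgeError):
    """A stratum label cannot be sanitized to a non-empty file-name token."""
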