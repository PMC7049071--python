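"""Exception hierarchy.

``ValidationError`` marks structurally invalid inputs (bad probabilities,
mismatched labels, malformed tables); ``DomainError`` marks inputs that are
structurally fine but put the requested quantity outside its domain (an
infinite divergence, a zero pooled standard deviation).
"""


class JSDBalanceError(ValueError):
    """Base class for all errors raised by this package."""


class ValidationError(JSDBalanceError):
    """Input fails a structural invariant (normalization, labels, counts)."""


class DomainError(JSDBalanceError):
    """Requested quantity is undefined or infinite for these inputs."""
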