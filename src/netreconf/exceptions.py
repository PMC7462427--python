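"""Package-specific error types."""


class InvalidConfigError(ValueError):
    """A simulation / windowing configuration violates its invariants."""


class EstimatorUndefinedError(ValueError):
    """An estimator was requested on inputs it is not defined for
    (e.g. cross-trial dwPLI with fewer than two trials)."""


class DegenerateLayerError(ValueError):
    """A network layer carries no weight, so the modularity null model
    (which divides by the layer's total weight) is undefined."""
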