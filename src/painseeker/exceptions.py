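"""Exception types shared across the package."""


class DimensionError(ValueError):
    """Array shape disagrees with what an operation expects."""


class InvalidGridError(ValueError):
    """Region grid is degenerate (fewer than 2 regions)."""


class SchemaError(ValueError):
    """A table row or annotation value violates the declared schema."""


class ProtocolError(ValueError):
    """Evaluation protocol precondition violated (e.g. a single subject)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. K_h >= K, undersized LBP cells)."""


class LayoutError(ValueError):
    """Synthetic face layout cannot fit disjoint AU patches."""


class InvalidImageError(ValueError):
    """Image too small or malformed for preprocessing."""


class InvalidBatchError(ValueError):
    """Empty or misaligned training batch."""


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimisation."""
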