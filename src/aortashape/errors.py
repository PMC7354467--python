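"""Exception hierarchy shared across the pipeline."""


class AortaShapeError(Exception):
    """Base class for all package errors."""


class MeshValidationError(AortaShapeError):
    """Surface mesh violates a geometric invariant (degenerate faces, bad indices, ...)."""


class CohortError(AortaShapeError):
    """Cohort table violates its schema (duplicate ids, unknown valve label, ...)."""


class TopologyError(AortaShapeError):
    """Mesh does not have the topology an operation requires (e.g. not an open tube)."""


class DegenerateInputError(AortaShapeError):
    """Input is too degenerate for the operation (too few points, collinear cloud, ...)."""


class ConfigError(AortaShapeError):
    """Pipeline configuration value out of its documented range."""
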