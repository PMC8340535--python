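"""Exception hierarchy shared across the pipeline."""


class MedinetError(Exception):
    """Base class for all package errors."""


class FormatError(MedinetError):
    """Malformed input table (missing column, unparseable field)."""


class EmptyNetworkError(MedinetError):
    """Edge table produced no usable network."""


class StructureError(MedinetError):
    """Graph violates a structural requirement (e.g. zero out-degree)."""


class ParameterError(MedinetError):
    """Numeric parameter outside its documented range."""


class ValidationError(MedinetError):
    """Record- or table-level contract violation."""


class GenerationError(MedinetError):
    """Synthetic-data generation could not satisfy the configuration."""


class PipelineError(MedinetError):
    """Pipeline-level failure (e.g. no scoreable samples)."""
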