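"""Exception hierarchy shared by all pipeline stages."""


class ComodnetError(Exception):
    """Base class for all errors raised by comodnet."""


class InvalidDesignError(ComodnetError):
    """The study design is malformed (e.g. fewer than 2 samples per group)."""


class SpecError(ComodnetError):
    """A simulation specification is inconsistent (sizes, dangling references)."""


class InputError(ComodnetError):
    """Malformed input data: shape mismatches, bad values, parse failures."""


class NormalizationError(ComodnetError):
    """Normalization cannot be applied (e.g. a single-sample matrix)."""


class TransformError(ComodnetError):
    """A scale transform is invalid for the data (nonpositive values, wrong scale)."""


class ModelError(ComodnetError):
    """The linear model cannot be fitted on the given design."""


class ParameterError(ComodnetError):
    """A parameter is outside its valid range."""


class AlignmentError(ComodnetError):
    """Sample IDs of two objects that must be aligned do not match."""
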