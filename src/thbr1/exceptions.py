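"""Exception hierarchy used across the package."""


class ThbR1Error(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ThbR1Error, ValueError):
    """A physical parameter is outside its admissible domain."""


class IllConditionedModelError(ThbR1Error, ArithmeticError):
    """The parameter set makes a model quantity singular or unsolvable."""


class GeometryError(ThbR1Error, ValueError):
    """Volumes do not share a common grid / affine."""


class ConfigurationError(ThbR1Error, ValueError):
    """A run configuration is inconsistent or leaves nothing to fit."""


class InvalidDataError(ThbR1Error, ValueError):
    """Input data violate a precondition (e.g. non-positive R1 means)."""
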