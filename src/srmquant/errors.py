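"""Exception types shared across the pipeline."""


class InvalidInputError(ValueError):
    """An argument violates a documented precondition (bad volume, efficiency, ...)."""


class InvalidWindowError(ValueError):
    """An integration window falls outside the trace's time span."""


class InvalidDesignError(ValueError):
    """A calibration or batch design cannot support the requested fit."""


class InvalidCurveError(ValueError):
    """Quantification was attempted against a flagged-invalid calibration curve."""


class MissingStandardError(ValueError):
    """A sub-LOQ evaluation was requested without a usable authentic standard."""
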