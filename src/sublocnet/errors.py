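"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """Invalid user input: malformed files, inconsistent ids, bad parameters."""


class GeometryError(ValidationError):
    """A convolution/pooling stack collapses to a non-positive spatial size."""


class TrainingDivergedError(RuntimeError):
    """Training loss became NaN/Inf; message names the offending epoch."""
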