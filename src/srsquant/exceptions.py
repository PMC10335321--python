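"""Exception hierarchy for the srsquant pipeline."""


class SrsQuantError(Exception):
    """Base class for all srsquant errors."""


class ValidationError(SrsQuantError, ValueError):
    """Invalid parameter values or inconsistent inputs."""


class GenerationError(SrsQuantError, RuntimeError):
    """A synthetic phantom could not be generated under the given spec."""


class DegenerateInputError(SrsQuantError, ValueError):
    """Input carries no usable contrast (constant image/spectrum)."""


class SingularFitError(SrsQuantError, ValueError):
    """A least-squares problem is singular (degenerate design)."""


class FormatError(SrsQuantError, ValueError):
    """A file on disk does not match the expected format."""
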