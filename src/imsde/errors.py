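"""Exception types shared across the package."""


class HardwareLimitError(ValueError):
    """A requested waveform exceeds a configured hardware limit."""


class GeometryError(ValueError):
    """Events overlap or a timeline is malformed."""


class InfeasibleDesignError(RuntimeError):
    """A design target cannot be met; the message names the binding constraint."""


class InfeasibleContrastError(ValueError):
    """The preparation alone exceeds the requested effective echo time."""
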