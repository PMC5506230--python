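"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid parameter value; the message names the offending field."""


class StructuralError(ValueError):
    """Input data whose shape/annotation structure violates the pipeline contract."""
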