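"""Package exception types."""


class ConfigurationError(ValueError):
    """An input schedule, file, or parameter set is missing or inconsistent."""


class ModelLogicError(RuntimeError):
    """An operation was applied to a state where it is not defined."""
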