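class ConfigurationError(ValueError):
    """Raised when user-supplied configuration violates a precondition."""


class ContractError(ValueError):
    """Raised when an operation's input contract is violated."""
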