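"""Exception hierarchy shared by all ovbin modules."""


class OvbinError(Exception):
    """Base class for all errors raised by ovbin."""


class ParseError(OvbinError):
    """A record in an input file violates its format."""


class ConfigurationError(OvbinError):
    """A parameter or configuration value is invalid."""


class ContractError(OvbinError):
    """A caller violated an operation's precondition."""
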