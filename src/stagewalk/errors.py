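"""Exception hierarchy shared across the package."""


class StagewalkError(Exception):
    """Base class for all package errors."""


class InputFormatError(StagewalkError):
    """An input file is malformed or references an unknown molecule kind."""


class NetworkValidationError(StagewalkError):
    """A network violates a structural rule (edge-kind whitelist, dangling refs)."""


class ContractError(StagewalkError):
    """An argument violates a documented precondition."""
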