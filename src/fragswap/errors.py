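"""Exception hierarchy for fragswap."""


class FragswapError(Exception):
    """Base class for all fragswap errors."""


class InputError(FragswapError):
    """A molecule or file could not be parsed or failed sanitization."""


class ParameterError(FragswapError):
    """A parameter value violates a documented precondition."""


class ContractViolation(FragswapError):
    """An internal contract between operations was broken by the caller."""


class FormatError(FragswapError):
    """A serialized artifact (database file, catalog) is malformed."""


class SpliceError(FragswapError):
    """Joining a replacement fragment into a context produced an invalid molecule."""


class ScoreError(FragswapError):
    """A scoring function violated its contract (range, purity)."""


class ConfigError(FragswapError):
    """An unknown scorer, catalog entry, or configuration value was requested."""
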