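"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so that configuration
mistakes, malformed input files, and computational failures can be told
apart in shell pipelines.
"""


class TriadExprError(Exception):
    """Base class for all package errors."""


class ConfigError(TriadExprError):
    """Invalid parameter or configuration value (CLI exit code 2)."""


class ParseError(TriadExprError):
    """Malformed input file (CLI exit code 3)."""


class ComputeError(TriadExprError):
    """A computation could not be carried out on the given inputs (exit 4)."""
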