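"""Exception hierarchy shared across the package."""


class CoalabcError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CoalabcError, ValueError):
    """A scenario, catalog or run configuration is inconsistent or incomplete."""


class TopologyError(CoalabcError, ValueError):
    """A population-tree specification is not a valid rooted binary history."""


class InputError(CoalabcError, ValueError):
    """Input data do not satisfy an operation's preconditions."""


class VcfParseError(CoalabcError, ValueError):
    """A VCF record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
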