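"""Exception hierarchy.

All package errors derive from :class:`HemenetError` so callers can catch one
type at the CLI boundary; subclasses distinguish user-input problems from
configuration and internal-consistency problems (exit codes 1 vs 2).
"""


class HemenetError(Exception):
    """Base class for all errors raised by hemenet."""


class InputError(HemenetError, ValueError):
    """Malformed user data: bad sequence characters, empty sequences, parse failures."""


class ParameterError(HemenetError, ValueError):
    """A numeric parameter is out of its valid range."""


class SizingError(HemenetError, ValueError):
    """A request is infeasible for the given sizes (e.g. too many motifs for a sequence)."""


class ConfigurationError(HemenetError, ValueError):
    """Malformed patterns, unknown methods/formats, or invalid configuration files."""


class IntegrityError(HemenetError, ValueError):
    """Internal-consistency violation in inputs: duplicate ids, unknown genomes."""
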