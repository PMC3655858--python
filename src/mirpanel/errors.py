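"""Exception taxonomy shared across the pipeline stages.

Three families map onto the CLI exit codes: configuration problems
(bad config files / invalid field values), data problems (malformed or
insufficient input tables), and parameter problems (invalid analysis
options such as a fold-change cutoff below 1).
"""


class MirpanelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirpanelError, ValueError):
    """A config object or file is invalid; the message names the field."""


class DataError(MirpanelError, ValueError):
    """Input data violate a precondition (missing ids, too few samples...)."""


class ParameterError(MirpanelError, ValueError):
    """An analysis parameter is out of its valid range."""
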