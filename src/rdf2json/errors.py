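"""Exception hierarchy for the rdf2json tool."""


class Rdf2JsonError(Exception):
    """Base class for all errors raised by rdf2json."""


class InputError(Rdf2JsonError):
    """An input file is missing or unreadable."""


class ParseError(Rdf2JsonError):
    """The RDF source is syntactically invalid."""


class ConfigError(Rdf2JsonError):
    """Bad option value, e.g. an unrecognised file extension or style."""


class OutputError(Rdf2JsonError):
    """The destination cannot be written."""


class ContractError(Rdf2JsonError):
    """An API precondition was violated by the caller."""


class ValidationError(Rdf2JsonError):
    """A user-supplied value fails validation."""


class KeyCollisionError(ValidationError):
    """Two distinct JSON keys map to the same sanitized key."""
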