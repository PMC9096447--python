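"""Exception hierarchy shared across the pipeline stages."""


class BioTagmeError(Exception):
    """Base class for all package errors."""


class ParseError(BioTagmeError):
    """Malformed input file; message names the offending line."""


class IntegrityError(BioTagmeError):
    """Input violates a uniqueness or referential invariant."""


class ValidationError(BioTagmeError, ValueError):
    """A value is outside its documented range."""


class LookupFailure(BioTagmeError, KeyError):
    """An entity, page or anchor is unknown to the snapshot/graph."""
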