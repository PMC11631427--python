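"""Exception hierarchy for libramix."""


class LibramixError(Exception):
    """Base class for all libramix errors."""


class ParseError(LibramixError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(LibramixError, ValueError):
    """Input data violates a structural invariant (shapes, ids, value domain)."""


class DegenerateDataError(LibramixError, ValueError):
    """Data admits no interior maximum-likelihood estimate (e.g. zero variance)."""


class AlignmentError(LibramixError, ValueError):
    """Two per-cell structures do not share the same cell set."""
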