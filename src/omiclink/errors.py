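"""Exception hierarchy.

All user-facing failures derive from :class:`OmiclinkError` so the CLI can
catch one type, print the message, and exit nonzero.
"""


class OmiclinkError(Exception):
    """Base class for all omiclink errors."""


class FormatError(OmiclinkError):
    """A file violates its declared structure (duplicate headers, too few columns...)."""


class ParseError(OmiclinkError):
    """A cell could not be parsed; message carries row/column coordinates."""


class ValidationError(OmiclinkError):
    """An in-memory object violates an invariant; message names the field."""


class ResolutionError(OmiclinkError):
    """A reference (layer name, identifier column, phenotype) could not be resolved."""
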