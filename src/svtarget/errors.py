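"""Exception hierarchy shared across svtarget modules."""


class SvtargetError(Exception):
    """Base class for all svtarget errors."""


class ConfigurationError(SvtargetError, ValueError):
    """An invalid parameter or configuration field. The message names the field."""


class CoordinateError(SvtargetError, ValueError):
    """An interval falls outside its reference or is empty/inverted."""


class PlacementError(SvtargetError, ValueError):
    """A planted site does not fit inside its designated feature."""


class AnnotationError(SvtargetError, ValueError):
    """A malformed gene model (no transcripts, overlapping exons, ...)."""


class ConsistencyError(SvtargetError, ValueError):
    """Internally inconsistent inputs (e.g. counts on a zero-length feature class)."""


class EmptyInputError(SvtargetError, ValueError):
    """An input file or sequence that must be non-empty is empty."""


class ParseError(SvtargetError, ValueError):
    """A record could not be parsed. The message names the record."""
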