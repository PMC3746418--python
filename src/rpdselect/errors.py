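"""Exception hierarchy for rpdselect."""


class RpdSelectError(Exception):
    """Base class for all rpdselect errors."""


class NewickParseError(RpdSelectError):
    """Malformed Newick input; the message includes the position reported by the parser."""


class TreeValidationError(RpdSelectError):
    """Tree violates a structural requirement (duplicate leaves, missing or negative lengths)."""


class UnknownLeafError(RpdSelectError, KeyError):
    """A leaf label was requested that is not present in the tree."""


class UnsupportedTopologyError(RpdSelectError):
    """uRPD requested on a path through a polytomy without generalized mode."""


class TableFormatError(RpdSelectError):
    """A tabular input file is missing required columns or malformed."""
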