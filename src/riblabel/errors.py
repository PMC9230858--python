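"""Exception hierarchy shared by all riblabel stages."""


class RibLabelError(Exception):
    """Base class for all riblabel failures."""


class FormatError(RibLabelError):
    """Input file or metadata cannot be interpreted (corrupt slice, mixed
    orientation, contradictory geometry)."""


class ParameterError(RibLabelError):
    """A caller-supplied parameter violates an operation's precondition."""


class ProcessingError(RibLabelError):
    """A pipeline stage could not complete on otherwise valid input
    (e.g. no vertebra detection available for a slice)."""
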