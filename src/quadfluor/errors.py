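"""Exception types raised across the pipeline."""


class QuadfluorError(Exception):
    """Base class for pipeline errors."""


class ValidationError(QuadfluorError, ValueError):
    """A domain object violates one of its invariants."""


class PlacementError(QuadfluorError, RuntimeError):
    """Cell placement by rejection sampling exhausted its retry budget."""


class ChannelMappingError(QuadfluorError, ValueError):
    """Channels of an on-disk image cannot be mapped to markers unambiguously."""


class SchemaError(QuadfluorError, ValueError):
    """A table is missing required columns."""


class RoiOverlapError(QuadfluorError, ValueError):
    """Two cell ROIs claim the same pixels."""
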