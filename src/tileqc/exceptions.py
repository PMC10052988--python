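"""Exception hierarchy shared across the toolkit."""


class TileQCError(Exception):
    """Base class for all toolkit errors."""


class InvalidSpecError(TileQCError, ValueError):
    """A tile/slide/architecture specification violates its invariants."""


class InvalidArgumentError(TileQCError, ValueError):
    """An operation was called with out-of-contract arguments."""


class DegenerateInputError(TileQCError, ValueError):
    """Input carries too little structure for the operation (e.g. a blank
    tile offered to stain-vector estimation, or a rank-1 OD cloud)."""


class FormatError(TileQCError, ValueError):
    """A raster file is not in a supported format."""
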