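"""Exception hierarchy shared by all mosaicfix stages."""


class MosaicfixError(Exception):
    """Base class for all mosaicfix errors."""


class InvalidParameterError(MosaicfixError, ValueError):
    """A parameter is outside its valid domain."""


class InvalidInputError(MosaicfixError, ValueError):
    """Input data is malformed (NaN, non-finite, wrong dtype)."""


class GeometryError(MosaicfixError, ValueError):
    """Shapes, grid indices, or crop windows are inconsistent."""


class EmptyInputError(MosaicfixError, ValueError):
    """An operation received an empty tile/link selection."""


class DegenerateInputError(MosaicfixError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all zero)."""


class ConnectivityError(MosaicfixError, ValueError):
    """The tile link graph does not connect all tiles."""


class InsufficientDataError(MosaicfixError, ValueError):
    """Too few observations for the requested statistic."""


class StageError(MosaicfixError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original!r}")
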