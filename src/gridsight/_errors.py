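"""Exception hierarchy shared across the pipeline stages."""


class GridSightError(Exception):
    """Base class for all gridsight errors."""


class InvalidInputError(GridSightError, ValueError):
    """Non-finite or out-of-contract numeric input."""


class ShapeError(GridSightError, ValueError):
    """Array/image dimensions do not match the declared contract."""


class DegenerateGeometryError(GridSightError):
    """Geometry admits no solution (e.g. zero/negative stereo disparity)."""


class InvalidParameterError(GridSightError, ValueError):
    """Parameter outside its admissible range."""


class EmptySceneError(GridSightError):
    """The object to render is entirely outside both camera frusta."""


class TooSmallError(GridSightError, ValueError):
    """Requested output image would be smaller than the supported minimum."""


class InvalidBBoxError(GridSightError, ValueError):
    """Bounding box does not overlap the image."""


class AmbiguityError(GridSightError):
    """Grid orientation cannot be disambiguated (no usable tail evidence)."""


class ContractError(GridSightError):
    """Caller violated an inter-stage contract (frame tags, validity masks...)."""


class InsufficientCorrespondencesError(GridSightError):
    """Too few mutually visible keypoints to triangulate the grid."""


class LabelFormatError(GridSightError, ValueError):
    """A label file line could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(GridSightError, ValueError):
    """Configuration schema violation; message names the offending key."""
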