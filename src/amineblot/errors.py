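"""Exception hierarchy shared across the package.

Two broad families matter to the CLI: configuration/usage problems
(exit code 2) and data/validation problems (exit code 3).
"""


class AmineblotError(Exception):
    """Base class for all package errors."""


class ConfigError(AmineblotError):
    """Invalid configuration: unknown keys, bad values, malformed files."""


class DataError(AmineblotError):
    """Invalid data passed to an operation."""


class ShapeError(DataError):
    """Image or array dimensions do not match the contract."""


class CoordinateError(DataError):
    """A coordinate lies outside the image."""


class DetectionError(DataError):
    """Grid detection failed; carries the missing cells."""

    def __init__(self, message: str, missing_cells: list[tuple[int, int]] | None = None):
        super().__init__(message)
        self.missing_cells = missing_cells or []


class DegenerateModelError(DataError):
    """The calibration design or fitted model cannot support the operation."""


class LayoutError(DataError):
    """Synthetic fixture geometry is inconsistent (e.g. trace crosses the grid)."""


class AlignmentError(DataError):
    """Overlay transform leaves no overlap between the two images."""
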