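"""Exception hierarchy shared across the pipeline stages."""


class FetAdcError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FetAdcError):
    """Invalid inputs or parameters (precondition failures)."""


class GridMismatchError(ValidationError):
    """Two grids that must be congruent (shape + spacing) are not."""


class EmptyMaskError(ValidationError):
    """A statistic was requested over a mask with zero voxels."""


class GeometryError(ValidationError):
    """Phantom geometry is inconsistent (e.g. tumor outside the brain)."""


class IOFailure(FetAdcError):
    """File input/output failed; carries the offending path."""

    def __init__(self, path, message):
        self.path = str(path)
        super().__init__(f"{message}: {self.path}")
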