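"""Exception hierarchy shared across the pipeline."""


class CryoHTError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CryoHTError, ValueError):
    """A parameter or input value violates a documented contract."""


class GeometryError(CryoHTError, ValueError):
    """A phantom does not fit the requested voxel grid."""


class FormatError(CryoHTError, ValueError):
    """An on-disk file is malformed or missing required metadata."""


class NoCellDetectedError(CryoHTError, RuntimeError):
    """Segmentation found no cell voxels after cleaning."""
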