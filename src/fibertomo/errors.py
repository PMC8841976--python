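"""Exception types shared across the pipeline stages."""


class FibertomoError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(FibertomoError, ValueError):
    """A phantom spec or run config violates its invariants."""


class DegenerateVolumeError(FibertomoError, ValueError):
    """A volume has no intensity contrast; no threshold separates anything."""


class EmptyParticleSetError(FibertomoError, ValueError):
    """An operation that requires at least one particle received none."""


class EmptySegmentationError(FibertomoError, ValueError):
    """Thresholding a density map produced no foreground structure."""


class EmptySkeletonError(FibertomoError, ValueError):
    """Topological thinning left no skeleton voxels to sample."""


class VolumeMismatchError(FibertomoError, ValueError):
    """Two volumes that must share shape and voxel size do not."""
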