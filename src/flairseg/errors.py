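"""Exception hierarchy.

Every contract violation in the pipeline raises a distinct, named error so
callers (and the CLI) can report which stage rejected its input.
"""


class FlairsegError(Exception):
    """Base class for all package errors."""


# --- volumes ---------------------------------------------------------------

class VolumeIOError(FlairsegError):
    """File missing, unreadable or not a valid NIfTI-1 image."""


class NotAVolumeError(VolumeIOError):
    """Image on disk does not have exactly 3 spatial axes."""


class NonBinaryMaskError(VolumeIOError):
    """Mask file contains values other than 0/1 beyond tolerance."""


class GridMismatchError(FlairsegError):
    """Two images do not share shape and voxel spacing."""


# --- phantom ---------------------------------------------------------------

class PlacementError(FlairsegError):
    """A lesion could not be placed inside the brain after bounded retries."""


class DegenerateSplitError(FlairsegError):
    """Train or test partition of a cohort would be empty."""


# --- preprocess ------------------------------------------------------------

class UnderdeterminedFitError(FlairsegError):
    """Fewer brain voxels than polynomial coefficients in a bias fit."""


class InvalidFieldError(FlairsegError):
    """Bias field non-positive where the volume is nonzero."""


class DegenerateHistogramError(FlairsegError):
    """Histogram landmarks are not strictly increasing."""


# --- autoencoder -----------------------------------------------------------

class ModelConfigError(FlairsegError):
    """Inconsistent architecture configuration."""


class NoPositiveTilesError(FlairsegError):
    """ROI sampling requested lesion-centred tiles but no lesion voxels exist."""


class TrainingDivergedError(FlairsegError):
    """Loss became non-finite during training (carries the epoch index)."""


class UntrainedModelError(FlairsegError):
    """Inference requested on a model that has no trained weights."""


# --- postprocess / metrics -------------------------------------------------

class InvalidProbabilityError(FlairsegError):
    """Probability map holds values outside [0, 1]."""


class UndefinedMetricError(FlairsegError):
    """Metric undefined for the given counts (e.g. empty reference)."""
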