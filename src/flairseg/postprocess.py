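"""Probability maps to final binary segmentations.

Two stages: threshold the tumor-class probability (strictly greater than,
default 0.5) and drop small connected components (default: components of
10 voxels or fewer, 26-connectivity). Component filtering runs in 3-D even
though inference is slice-wise — spurious detections are volumetric
objects, and residual-skull false positives in particular are small 3-D
specks this filter is meant to kill.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import InvalidProbabilityError
from .volumes import BinaryMask, Volume

__all__ = ["binarize", "filter_small_components", "segment", "CONNECTIVITY_STRUCTS"]

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def binarize(p: Volume, threshold: float = 0.5) -> BinaryMask:
    """Voxel is foreground iff its probability strictly exceeds ``threshold``."""
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    data = np.asarray(p.data)
    if data.min() < 0 or data.max() > 1:
        raise InvalidProbabilityError("invalid probability map: values outside [0, 1]")
    return BinaryMask(data=data > threshold, spacing=p.spacing, affine=p.affine.copy())


def filter_small_components(
    m: BinaryMask, min_voxels: int = 10, connectivity: int = 26
) -> BinaryMask:
    """Remove connected components of ``min_voxels`` voxels or fewer.

    Components of at least ``min_voxels + 1`` voxels survive unchanged, so
    the operation is idempotent and only ever removes voxels.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTS)}")
    labels, n = ndimage.label(m.data, structure=CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return m.with_data(m.data.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes > min_voxels
    keep[0] = False
    return m.with_data(keep[labels])


def segment(
    model,
    v: Volume,
    threshold: float = 0.5,
    min_voxels: int = 10,
    connectivity: int = 26,
) -> BinaryMask:
    """Full inference: predict -> binarize -> filter small components."""
    from .autoencoder import predict_volume

    prob = predict_volume(model, v)
    return filter_small_components(
        binarize(prob, threshold), min_voxels=min_voxels, connectivity=connectivity
    )
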