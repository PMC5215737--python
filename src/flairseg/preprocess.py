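"""Intensity preprocessing: bias-field correction and Nyul standardization.

Two problems plague raw FLAIR intensities. First, scanner coil physics adds
a smooth multiplicative inhomogeneity (the *bias field*). Second, MRI has no
standard intensity scale, so the "same" tissue lands at different raw values
across scans. Both must be fixed before a single intensity-driven model can
segment a cohort.

Bias correction here fits a low-order 3-D polynomial to log-intensities over
the brain mask and divides it out. This is a deliberately simple surrogate
for full B-spline N4: it captures the low-frequency component that matters,
keeps the package self-contained, and externally N4-corrected input can be
supplied instead (the fit is then a near-no-op).

Standardization follows the Nyul histogram-landmark method: learn the mean
landmark intensities (at fixed percentiles, over brain voxels) of a training
cohort on a common standard scale, then map each new volume onto that scale
by piecewise-linear interpolation between its own landmarks and the learned
standard positions. Beyond the outermost landmarks the terminal segments are
extended linearly — never clipped — so extreme hyperintensities (the
segmentation target) keep their ordering.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateHistogramError, InvalidFieldError, UnderdeterminedFitError
from .volumes import BinaryMask, Volume, require_same_grid

__all__ = [
    "BiasField",
    "fit_bias_field",
    "correct_bias",
    "StandardizationModel",
    "DEFAULT_PERCENTILES",
    "fit_standardization",
    "apply_standardization",
]

DEFAULT_PERCENTILES: tuple[float, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
DEFAULT_STANDARD_RANGE: tuple[float, float] = (0.0, 100.0)


# --------------------------------------------------------------------------
# bias field
# --------------------------------------------------------------------------

def _poly_exponents(order: int) -> list[tuple[int, int, int]]:
    """Monomial exponents (i, j, k) with total degree <= order."""
    return [
        (i, j, k)
        for i, j, k in itertools.product(range(order + 1), repeat=3)
        if i + j + k <= order
    ]


def _design_matrix(coords: np.ndarray, exponents: list[tuple[int, int, int]]) -> np.ndarray:
    cols = [
        coords[:, 0] ** i * coords[:, 1] ** j * coords[:, 2] ** k for i, j, k in exponents
    ]
    return np.stack(cols, axis=1)


def _normalized_coords(shape: tuple[int, int, int], idx: tuple[np.ndarray, ...]) -> np.ndarray:
    """Voxel indices mapped to [-1, 1] per axis (stable polynomial basis)."""
    out = np.empty((idx[0].size, 3))
    for ax in range(3):
        n = shape[ax]
        out[:, ax] = 2.0 * idx[ax] / max(n - 1, 1) - 1.0
    return out


@dataclass
class BiasField:
    """Low-order 3-D polynomial model of log multiplicative bias.

    ``coefficients`` act on monomials of normalized coordinates in the
    order given by ``_poly_exponents(order)``; the evaluated field is
    ``exp(polynomial)`` rescaled to mean 1 over the fitted brain mask.
    """

    coefficients: np.ndarray
    order: int
    shape: tuple[int, int, int]
    log_offset: float = 0.0  # subtracted from the polynomial before exp

    def evaluate(self) -> np.ndarray:
        """Evaluate the (strictly positive) field on the full grid."""
        idx = np.indices(self.shape).reshape(3, -1)
        coords = _normalized_coords(self.shape, tuple(idx))
        A = _design_matrix(coords, _poly_exponents(self.order))
        logf = A @ self.coefficients - self.log_offset
        return np.exp(logf).reshape(self.shape)


def fit_bias_field(v: Volume, brain: BinaryMask, order: int = 2) -> BiasField:
    """Least-squares fit of a degree-``order`` log-polynomial bias over the brain.

    The returned field has mean 1 over the brain mask, so dividing it out
    preserves mean brain brightness.
    """
    require_same_grid(v, brain, "volume and brain mask")
    idx = np.nonzero(brain.data)
    n_vox = idx[0].size
    if n_vox == 0:
        raise ValueError("brain mask is empty")
    vals = v.data[idx].astype(np.float64)
    if np.any(vals <= 0):
        raise ValueError("intensities must be positive within the brain mask")
    exponents = _poly_exponents(order)
    if n_vox < len(exponents):
        raise UnderdeterminedFitError(
            f"underdetermined fit: {n_vox} brain voxels < {len(exponents)} coefficients"
        )
    coords = _normalized_coords(v.data.shape, idx)
    A = _design_matrix(coords, exponents)
    coefs, *_ = np.linalg.lstsq(A, np.log(vals), rcond=None)
    # normalize: mean of exp(poly) over the mask = 1
    log_offset = float(np.log(np.mean(np.exp(A @ coefs))))
    return BiasField(coefficients=coefs, order=order, shape=v.data.shape, log_offset=log_offset)


def correct_bias(v: Volume, f: BiasField) -> Volume:
    """Divide out the evaluated bias field; zero voxels stay exactly zero."""
    field_ = f.evaluate()
    nonzero = v.data != 0
    if np.any(field_[nonzero] <= 0):
        raise InvalidFieldError("invalid field: non-positive value on a nonzero voxel")
    out = np.zeros_like(v.data, dtype=np.float64)
    out[nonzero] = v.data[nonzero] / field_[nonzero]
    return v.with_data(out.astype(v.data.dtype))


# --------------------------------------------------------------------------
# Nyul standardization
# --------------------------------------------------------------------------

@dataclass
class StandardizationModel:
    """Learned histogram-landmark table mapping raw intensities to a standard scale."""

    landmark_percentiles: tuple[float, ...]
    standard_positions: np.ndarray
    standard_range: tuple[float, float] = DEFAULT_STANDARD_RANGE

    def __post_init__(self) -> None:
        p = np.asarray(self.landmark_percentiles, dtype=float)
        if p.ndim != 1 or p.size < 2 or np.any(np.diff(p) <= 0) or p[0] <= 0 or p[-1] >= 100:
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        s = np.asarray(self.standard_positions, dtype=float)
        if s.shape != p.shape:
            raise ValueError("one standard position per percentile required")
        if np.any(np.diff(s) <= 0):
            raise DegenerateHistogramError("degenerate histogram: standard positions not increasing")
        lo, hi = self.standard_range
        if s[0] < lo - 1e-9 or s[-1] > hi + 1e-9:
            raise ValueError("standard positions must lie within standard_range")
        self.landmark_percentiles = tuple(p)
        self.standard_positions = s

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "landmark_percentiles": list(self.landmark_percentiles),
                    "standard_positions": self.standard_positions.tolist(),
                    "standard_range": list(self.standard_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "StandardizationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            landmark_percentiles=tuple(d["landmark_percentiles"]),
            standard_positions=np.asarray(d["standard_positions"]),
            standard_range=tuple(d["standard_range"]),
        )


def _landmarks(v: Volume, brain: BinaryMask, percentiles: np.ndarray) -> np.ndarray:
    require_same_grid(v, brain, "volume and brain mask")
    vals = v.data[brain.data]
    if vals.size == 0:
        raise ValueError("brain mask is empty")
    lm = np.percentile(vals.astype(np.float64), percentiles)
    if np.any(np.diff(lm) <= 0):
        raise DegenerateHistogramError(
            "degenerate histogram: volume landmarks not strictly increasing"
        )
    return lm


def fit_standardization(
    volumes: list[Volume],
    brains: list[BinaryMask],
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    standard_range: tuple[float, float] = DEFAULT_STANDARD_RANGE,
) -> StandardizationModel:
    """Learn the standard scale from a training cohort.

    For each volume the landmark intensities at ``percentiles`` (over brain
    voxels) are linearly mapped so that the first/last landmark hit the ends
    of ``standard_range``; the standard positions are the across-volume means
    of the mapped landmarks.
    """
    if not volumes:
        raise ValueError("at least one training volume required")
    if len(volumes) != len(brains):
        raise ValueError("one brain mask per volume required")
    p = np.asarray(percentiles, dtype=float)
    lo, hi = standard_range
    mapped = []
    for v, b in zip(volumes, brains):
        lm = _landmarks(v, b, p)
        mapped.append(lo + (lm - lm[0]) * (hi - lo) / (lm[-1] - lm[0]))
    mean_positions = np.mean(mapped, axis=0)
    if np.any(np.diff(mean_positions) <= 0):
        raise DegenerateHistogramError("degenerate histogram: mean landmarks not monotone")
    return StandardizationModel(
        landmark_percentiles=tuple(p),
        standard_positions=mean_positions,
        standard_range=standard_range,
    )


def apply_standardization(
    v: Volume, brain: BinaryMask, m: StandardizationModel
) -> Volume:
    """Map a volume onto the standard scale.

    Piecewise-linear through (own landmark_i -> standard_position_i); the
    terminal segments are extended linearly outside [first, last] landmark.
    The map is non-decreasing, and outside-brain zeros are preserved.
    """
    p = np.asarray(m.landmark_percentiles, dtype=float)
    lm = _landmarks(v, brain, p)
    pos = m.standard_positions
    x = v.data.astype(np.float64)
    out = np.interp(x, lm, pos)
    # np.interp clips; extend terminal segments linearly instead
    lo_slope = (pos[1] - pos[0]) / (lm[1] - lm[0])
    hi_slope = (pos[-1] - pos[-2]) / (lm[-1] - lm[-2])
    below = x < lm[0]
    above = x > lm[-1]
    out[below] = pos[0] + (x[below] - lm[0]) * lo_slope
    out[above] = pos[-1] + (x[above] - lm[-1]) * hi_slope
    out[v.data == 0] = 0.0
    return v.with_data(out.astype(np.float32))
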