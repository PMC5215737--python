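"""Synthetic skull-stripped FLAIR-like phantoms with known lesion masks.

The generator emulates the appearance the segmentation pipeline is built
for: a brain (modelled as a centred ellipsoid of uniform baseline tissue
signal) containing one or more hyperintense ellipsoidal lesions, modulated
by a smooth multiplicative bias field, degraded by additive Gaussian noise,
and optionally contaminated by a thin bright residual-skull arc outside the
brain — the classic source of false positives when skull stripping fails.
All structure is analytic, so the ground-truth lesion mask is exact, and
generation is a pure function of ``(spec, seed)``.

Simulated raters apply voxel-wise independent Bernoulli errors to the true
mask with known sensitivity/specificity, which is exactly the generative
model STAPLE assumes — so rater-parameter recovery is a well-posed test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateSplitError, PlacementError
from .volumes import BinaryMask, Volume

__all__ = [
    "PhantomSpec",
    "RaterProfile",
    "Case",
    "Cohort",
    "generate_phantom",
    "simulate_raters",
    "generate_cohort",
    "derive_seed",
]

_BASELINE = 100.0  # baseline brain-tissue signal, arbitrary MRI units
_MAX_PLACEMENT_TRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``n_lesions`` may be a fixed count or an inclusive ``(lo, hi)`` range
    sampled per phantom. ``lesion_intensity`` is the fractional signal
    elevation of lesion over baseline tissue (0.6 means 60% brighter).
    ``bias_amplitude`` is the peak-to-trough multiplicative factor of the
    smooth bias field (1 = no bias). ``noise_sd`` is the additive Gaussian
    noise level in intensity units (baseline tissue is 100).
    """

    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int | tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[float, float] = (4.0, 8.0)  # mm
    lesion_intensity: float = 0.6
    noise_sd: float = 4.0
    bias_amplitude: float = 1.2
    skull_ring: bool = False
    skull_ring_intensity: float = 1.8  # relative to baseline
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ValueError("lesion radii must be positive and ordered")
        max_extent = min(s * d for s, d in zip(self.shape, self.spacing))
        if hi >= max_extent / 2:
            raise ValueError("lesion radius must be smaller than half the grid extent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must be >= 1")
        n = self.n_lesions
        if isinstance(n, tuple):
            if not (0 <= n[0] <= n[1]):
                raise ValueError("n_lesions range must be ordered and non-negative")
        elif n < 0:
            raise ValueError("n_lesions must be >= 0")


@dataclass(frozen=True)
class RaterProfile:
    """Per-rater performance: sensitivity ``p`` and specificity ``q``, both in (0, 1]."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for v, name in ((self.sensitivity, "sensitivity"), (self.specificity, "specificity")):
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def derive_seed(master: int, index: int) -> int:
    """Per-case seed from a master seed via a splitmix64-style mix.

    A fixed integer scheme (rather than stateful draws) so that case ``i``
    of a cohort is reproducible independently of how many cases precede it.
    """
    z = (master * 0x9E3779B97F4A7C15 + (index + 1) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    z ^= z >> 31
    return int(z % (2**31 - 1))


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Boolean ellipsoid (x-c)^T diag(1/a^2) (x-c) <= 1 on the voxel grid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _brain_geometry(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    center = (np.asarray(shape, dtype=np.float64) - 1) / 2
    semi = np.asarray(shape, dtype=np.float64) * 0.42
    return center, semi


def _smooth_bias(shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative bias field: exp of a random degree-2 polynomial,
    centred and scaled so that max/min over the grid equals ``amplitude``."""
    if amplitude == 1.0:
        return np.ones(shape)
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    terms = [X, Y, Z, X * Y, X * Z, Y * Z, X * X, Y * Y, Z * Z]
    coefs = rng.standard_normal(len(terms))
    poly = sum(c * t for c, t in zip(coefs, terms))
    span = poly.max() - poly.min()
    if span < 1e-12:
        return np.ones(shape)
    poly = poly * (np.log(amplitude) / span)
    poly -= poly.mean()
    return np.exp(poly)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask]:
    """Generate one phantom and its exact lesion mask.

    Construction order: two-level tissue (baseline + lesions) -> multiplicative
    bias -> additive noise inside the head -> optional skull arc. Outside-head
    voxels are exactly zero, matching skull-stripped input.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    b_center, b_semi = _brain_geometry(shape)
    brain = _ellipsoid(shape, b_center, b_semi)

    n = spec.n_lesions
    n_lesions = int(rng.integers(n[0], n[1] + 1)) if isinstance(n, tuple) else int(n)

    lesion_mask = np.zeros(shape, dtype=bool)
    sp = np.asarray(spec.spacing)
    for _ in range(n_lesions):
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            radii_mm = rng.uniform(*spec.lesion_radius_range, size=3)
            semi_vox = radii_mm / sp
            # admissible centres: lesion ellipsoid fully inside the brain ellipsoid
            margin = b_semi - semi_vox
            if np.any(margin <= 1.0):
                continue
            u = rng.uniform(-1, 1, size=3)
            if np.sum(u**2) > 1:
                continue
            center = b_center + u * (margin - 1.0)
            les = _ellipsoid(shape, center, semi_vox)
            if not les.any() or np.any(les & ~brain):
                continue
            # keep lesions separated (no touching under 26-connectivity)
            grown = ndimage.binary_dilation(les, structure=np.ones((3, 3, 3), dtype=bool))
            if np.any(grown & lesion_mask):
                continue
            lesion_mask |= les
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placement failure: could not place lesion inside brain after "
                f"{_MAX_PLACEMENT_TRIES} tries"
            )

    data = np.zeros(shape, dtype=np.float64)
    data[brain] = _BASELINE
    data[lesion_mask] = _BASELINE * (1.0 + spec.lesion_intensity)
    data *= _smooth_bias(shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=shape)
        data[brain] += noise[brain]
        np.clip(data, 0.0, None, out=data)

    if spec.skull_ring:
        # thin partial bright shell just outside the brain: residual skull
        shell = _ellipsoid(shape, b_center, b_semi * 1.12) & ~_ellipsoid(
            shape, b_center, b_semi * 1.04
        )
        # keep only an angular arc so the ring is partial, as real failures are
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        theta = np.arctan2(grids[1] - b_center[1], grids[0] - b_center[0])
        theta0 = rng.uniform(-np.pi, np.pi)
        arc = np.cos(theta - theta0) > 0.3
        shell &= np.broadcast_to(arc, shape)
        ring_val = _BASELINE * spec.skull_ring_intensity
        if spec.noise_sd > 0:
            data[shell] = ring_val + rng.normal(0.0, spec.noise_sd, size=int(shell.sum()))
        else:
            data[shell] = ring_val

    vol = Volume(data=data.astype(np.float32), spacing=spec.spacing)
    mask = BinaryMask(data=lesion_mask, spacing=spec.spacing)
    return vol, mask


def brain_mask_of(v: Volume) -> BinaryMask:
    """Foreground mask of nonzero voxels (volumes are skull-stripped)."""
    return BinaryMask(data=v.data > 0, spacing=v.spacing, affine=v.affine.copy())


def simulate_raters(
    truth: BinaryMask,
    profiles: list[RaterProfile],
    brain: BinaryMask,
    seed: int,
) -> list[BinaryMask]:
    """Simulate imperfect raters tracing ``truth`` within ``brain``.

    Each rater independently misses a true lesion voxel with probability
    1 - sensitivity and falsely marks a background brain voxel with
    probability 1 - specificity. Voxels outside the brain stay 0.
    """
    if not profiles:
        raise ValueError("at least one rater profile required")
    if np.any(truth.data & ~brain.data):
        raise ValueError("truth mask must lie within the brain mask")
    rng = np.random.default_rng(seed)
    out = []
    bg = brain.data & ~truth.data
    for prof in profiles:
        r = np.zeros(truth.shape, dtype=bool)
        u = rng.random(truth.shape)
        r[truth.data] = u[truth.data] < prof.sensitivity
        r[bg] = u[bg] >= prof.specificity
        out.append(truth.with_data(r))
    return out


@dataclass
class Case:
    """One cohort member: phantom volume, exact truth, head mask."""

    case_id: str
    volume: Volume
    truth: BinaryMask
    brain: BinaryMask
    seed: int


@dataclass
class Cohort:
    """A list of cases with a disjoint, exhaustive train/test partition."""

    cases: list[Case]
    train_idx: list[int]
    test_idx: list[int]
    master_seed: int

    @property
    def train(self) -> list[Case]:
        return [self.cases[i] for i in self.train_idx]

    @property
    def test(self) -> list[Case]:
        return [self.cases[i] for i in self.test_idx]


def generate_cohort(
    n_cases: int,
    spec: PhantomSpec,
    train_fraction: float,
    seed: int,
) -> Cohort:
    """Generate ``n_cases`` independent phantoms and split them train/test.

    Per-case seeds derive from the master seed by :func:`derive_seed`, so
    the cohort is reproducible case-by-case. The first
    ``round(n_cases * train_fraction)`` cases form the training partition.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(n_cases * train_fraction))
    if n_train == 0 or n_train == n_cases:
        raise DegenerateSplitError(
            f"degenerate split: {n_train} train / {n_cases - n_train} test from {n_cases} cases"
        )
    cases = []
    for i in range(n_cases):
        case_seed = derive_seed(seed, i)
        vol, truth = generate_phantom(replace(spec, seed=case_seed))
        # head mask from the known geometry, not thresholding, so noise cannot erode it
        brain = _ellipsoid(tuple(spec.shape), *_brain_geometry(tuple(spec.shape)))
        cases.append(
            Case(
                case_id=f"case_{i:03d}",
                volume=vol,
                truth=truth,
                brain=BinaryMask(data=brain, spacing=spec.spacing),
                seed=case_seed,
            )
        )
    return Cohort(
        cases=cases,
        train_idx=list(range(n_train)),
        test_idx=list(range(n_train, n_cases)),
        master_seed=seed,
    )
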