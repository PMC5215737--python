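"""Bias-field surrogate and Nyul histogram-landmark standardization."""

import numpy as np
import pytest

from flairseg.errors import DegenerateHistogramError, UnderdeterminedFitError
from flairseg.phantom import PhantomSpec, brain_mask_of, generate_cohort, generate_phantom
from flairseg.preprocess import (
    DEFAULT_PERCENTILES,
    StandardizationModel,
    apply_standardization,
    correct_bias,
    fit_bias_field,
    fit_standardization,
)
from flairseg.volumes import BinaryMask, Volume


def _ellipsoid_volume(value=100.0, shape=(24, 24, 16)):
    spec = PhantomSpec(
        shape=shape, n_lesions=0, lesion_radius_range=(3.0, 5.0),
        noise_sd=0.0, bias_amplitude=1.0, seed=0,
    )
    vol, _ = generate_phantom(spec)
    vol.data = vol.data / 100.0 * value
    return vol, brain_mask_of(vol)


# --------------------------------------------------------------------------
# bias field
# --------------------------------------------------------------------------

def test_constant_volume_gives_unit_field():
    vol, brain = _ellipsoid_volume()
    f = fit_bias_field(vol, brain, order=2)
    assert np.max(np.abs(f.evaluate()[brain.data] - 1.0)) < 1e-6


def test_known_linear_ramp_is_removed():
    """Multiplicative 0.9 -> 1.1 ramp: order-1 correction cuts the
    coefficient of variation of uniform tissue by at least 90%."""
    vol, brain = _ellipsoid_volume()
    nx = vol.data.shape[0]
    ramp = np.linspace(0.9, 1.1, nx)[:, None, None]
    biased = vol.with_data(vol.data * ramp)
    f = fit_bias_field(biased, brain, order=1)
    corrected = correct_bias(biased, f)

    def cov(v):
        vals = v.data[brain.data]
        return vals.std() / vals.mean()

    assert cov(corrected) <= 0.1 * cov(biased)


def test_order_zero_field_is_identity_after_normalization():
    vol, brain = _ellipsoid_volume()
    ramped = vol.with_data(vol.data * np.linspace(0.8, 1.2, vol.data.shape[0])[:, None, None])
    f = fit_bias_field(ramped, brain, order=0)
    assert np.max(np.abs(f.evaluate() - 1.0)) < 1e-12
    corrected = correct_bias(ramped, f)
    assert np.allclose(corrected.data, ramped.data)


def test_correction_preserves_mean_brain_intensity():
    spec = PhantomSpec(seed=8)  # noisy, biased phantom
    vol, _ = generate_phantom(spec)
    brain = brain_mask_of(vol)
    f = fit_bias_field(vol, brain, order=2)
    corrected = correct_bias(vol, f)
    before = vol.data[brain.data].astype(np.float64).mean()
    after = corrected.data[brain.data].astype(np.float64).mean()
    # mean-1 field normalization preserves the mean to first order only:
    # E[v/f] - E[v] carries Jensen/covariance terms of order var(f) ~ 3e-3
    # for a bias amplitude of 1.2
    assert abs(after - before) / before < 5e-3


def test_background_zeros_preserved():
    spec = PhantomSpec(seed=8)
    vol, _ = generate_phantom(spec)
    brain = brain_mask_of(vol)
    corrected = correct_bias(vol, fit_bias_field(vol, brain, order=2))
    assert np.all(corrected.data[vol.data == 0] == 0)


def test_underdetermined_fit_rejected():
    vol, brain = _ellipsoid_volume()
    tiny = np.zeros_like(brain.data)
    idx = np.argwhere(brain.data)[:3]
    tiny[tuple(idx.T)] = True
    with pytest.raises(UnderdeterminedFitError):
        fit_bias_field(vol, BinaryMask(data=tiny), order=2)


# --------------------------------------------------------------------------
# standardization
# --------------------------------------------------------------------------

def _noisy_cases(n, seed=0, shape=(32, 32, 16)):
    coh = generate_cohort(
        max(n, 2),
        PhantomSpec(shape=shape, lesion_radius_range=(3.0, 5.0), seed=0),
        0.5,
        seed=seed,
    )
    return [(c.volume, c.brain) for c in coh.cases[:n]]


def test_self_consistency_single_volume():
    (vol, brain), = _noisy_cases(1)
    m = fit_standardization([vol], [brain])
    out = apply_standardization(vol, brain, m)
    p = np.asarray(m.landmark_percentiles)
    landmarks_after = np.percentile(out.data[brain.data].astype(np.float64), p)
    assert np.allclose(landmarks_after, m.standard_positions, atol=1e-3)


def test_shift_invariance_across_volumes():
    """A +100 intensity shift of the same volume standardizes identically."""
    (vol, brain), = _noisy_cases(1)
    shifted = vol.with_data(np.where(vol.data > 0, vol.data + 100.0, 0.0))
    m = fit_standardization([vol, shifted], [brain, brain])
    a = apply_standardization(vol, brain, m)
    b = apply_standardization(shifted, brain, m)
    p = np.asarray(m.landmark_percentiles)
    la = np.percentile(a.data[brain.data], p)
    lb = np.percentile(b.data[brain.data], p)
    assert np.allclose(la, lb, atol=1e-3)


def test_two_landmarks_is_a_single_linear_rescale():
    (vol, brain), = _noisy_cases(1)
    m = fit_standardization([vol], [brain], percentiles=(1.0, 99.0))
    out = apply_standardization(vol, brain, m)
    vals = vol.data[brain.data].astype(np.float64)
    lo, hi = np.percentile(vals, [1, 99])
    expected = (vals - lo) * 100.0 / (hi - lo)
    assert np.allclose(out.data[brain.data], expected, atol=1e-3)


def test_mapping_is_monotone():
    cases = _noisy_cases(2)
    m = fit_standardization([c[0] for c in cases], [c[1] for c in cases])
    vol, brain = cases[0]
    out = apply_standardization(vol, brain, m)
    order = np.argsort(vol.data[brain.data], kind="stable")
    mapped = out.data[brain.data][order]
    # float32 storage can invert near-ties by ~1e-3 at intensities ~100
    assert np.all(np.diff(mapped.astype(np.float64)) >= -2e-3)


def test_dispersion_reduction_under_scale_and_offset(rng):
    """Random per-case scale/offset: post-standardization across-case SD of
    every landmark falls to <= 10% of its pre-standardization value."""
    cases = _noisy_cases(5, seed=6)
    vols, brains = [], []
    for vol, brain in cases:
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(-20.0, 50.0)
        data = np.where(vol.data > 0, a * vol.data + b, 0.0)
        vols.append(vol.with_data(np.clip(data, 1e-3, None) * (vol.data > 0)))
        brains.append(brain)
    m = fit_standardization(vols, brains)
    out = [apply_standardization(v, b, m) for v, b in zip(vols, brains)]
    p = np.asarray(m.landmark_percentiles)
    pre = np.array([np.percentile(v.data[b.data], p) for v, b in zip(vols, brains)])
    post = np.array([np.percentile(v.data[b.data], p) for v, b in zip(out, brains)])
    assert np.all(post.std(axis=0) <= 0.10 * pre.std(axis=0))


def test_idempotent_on_standard_scale():
    cases = _noisy_cases(3, seed=9)
    vols = [c[0] for c in cases]
    brains = [c[1] for c in cases]
    m = fit_standardization(vols, brains)
    std_vols = [apply_standardization(v, b, m) for v, b in zip(vols, brains)]
    m2 = fit_standardization(std_vols, brains)
    twice = [apply_standardization(v, b, m2) for v, b in zip(std_vols, brains)]
    scale = m.standard_range[1] - m.standard_range[0]
    p = np.asarray(m.landmark_percentiles)
    for once, again, b in zip(std_vols, twice, brains):
        l1 = np.percentile(once.data[b.data].astype(np.float64), p)
        l2 = np.percentile(again.data[b.data].astype(np.float64), p)
        assert np.max(np.abs(l1 - l2)) < 1e-3 * scale


def test_degenerate_histogram_rejected():
    flat = Volume(data=np.where(np.arange(27).reshape(3, 3, 3) >= 0, 5.0, 0.0))
    brain = BinaryMask(data=np.ones((3, 3, 3), dtype=bool))
    with pytest.raises(DegenerateHistogramError):
        fit_standardization([flat], [brain])


def test_model_json_round_trip(tmp_path):
    cases = _noisy_cases(1)
    m = fit_standardization([cases[0][0]], [cases[0][1]])
    m.to_json(tmp_path / "m.json")
    back = StandardizationModel.from_json(tmp_path / "m.json")
    assert back.landmark_percentiles == m.landmark_percentiles
    assert np.allclose(back.standard_positions, m.standard_positions)
    assert back.standard_range == m.standard_range
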