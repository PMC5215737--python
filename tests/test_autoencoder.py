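"""Architecture contracts, pool/unpool index identity, ROI sampling, training."""

import numpy as np
import pytest

from flairseg.autoencoder import (
    ModelConfig,
    build_model,
    load_model,
    predict_volume,
    sample_rois,
    save_model,
    train_model,
)
from flairseg.errors import ModelConfigError, NoPositiveTilesError, UntrainedModelError
from flairseg.nn import MaxPool2x2, unpool_scatter
from flairseg.phantom import Case, PhantomSpec, brain_mask_of, generate_phantom


def _tiny_cases(n=2, **spec_kw):
    cases = []
    for i in range(n):
        spec = PhantomSpec(
            shape=(32, 32, 16), lesion_radius_range=(3.0, 5.0), seed=100 + i, **spec_kw
        )
        vol, truth = generate_phantom(spec)
        brain = brain_mask_of(vol)
        brain.data |= truth.data
        cases.append(Case(case_id=f"c{i}", volume=vol, truth=truth, brain=brain, seed=i))
    return cases


# --------------------------------------------------------------------------
# architecture
# --------------------------------------------------------------------------

def test_softmax_channels_sum_to_one(rng):
    m = build_model(ModelConfig(), seed=0)
    x = rng.normal(0, 1, size=(3, 16, 16)).astype(np.float32)
    prob = m.forward(x)
    assert prob.shape == (3, 16, 16, 2)
    assert np.max(np.abs(prob.sum(axis=-1) - 1.0)) < 1e-6


def test_shape_equivariance():
    m = build_model(ModelConfig(), seed=0)
    for h, w in [(16, 16), (24, 40), (64, 64)]:
        prob = m.forward(np.zeros((1, h, w), dtype=np.float32))
        assert prob.shape == (1, h, w, 2)


def test_same_seed_identical_forward(rng):
    x = rng.normal(0, 1, size=(2, 16, 16)).astype(np.float32)
    a = build_model(ModelConfig(), seed=5).forward(x)
    b = build_model(ModelConfig(), seed=5).forward(x)
    assert np.array_equal(a, b)


def test_inconsistent_config_rejected():
    with pytest.raises(ModelConfigError):
        ModelConfig(n_encoder_convs=7, pooling_blocks=(2, 2))


def test_pool_unpool_index_identity_vs_brute_force(rng):
    """unpool(pool(x)) reproduces x exactly at argmax positions, 0 elsewhere,
    checked against an explicit 2x2 window scan."""
    x = rng.normal(0, 1, size=(2, 8, 8, 3)).astype(np.float32)
    pool = MaxPool2x2()
    pooled, idx = pool.forward(x, train=True)
    restored = unpool_scatter(pooled, idx, x.shape)

    expected = np.zeros_like(x)
    for n in range(x.shape[0]):
        for c in range(x.shape[3]):
            for i in range(0, 8, 2):
                for j in range(0, 8, 2):
                    win = x[n, i : i + 2, j : j + 2, c]
                    di, dj = np.unravel_index(np.argmax(win), (2, 2))
                    assert pooled[n, i // 2, j // 2, c] == win[di, dj]
                    expected[n, i + di, j + dj, c] = win[di, dj]
    assert np.array_equal(restored, expected)


# --------------------------------------------------------------------------
# ROI sampling
# --------------------------------------------------------------------------

def test_sample_count_and_tile_size():
    rois = sample_rois(_tiny_cases(), n_total=100, tile_size=10, seed=0)
    assert len(rois) == 100
    assert rois.patches.shape == (100, 10, 10)
    assert rois.labels.shape == (100, 10, 10)


def test_tumor_fraction_one_centres_on_lesions():
    cases = _tiny_cases()
    rois = sample_rois(cases, n_total=50, tumor_fraction=1.0, seed=1)
    by_id = {c.case_id: c for c in cases}
    for (cid, z, x, y) in rois.provenance:
        assert by_id[cid].truth.data[x, y, z]


def test_tumor_fraction_recount():
    """Half the tiles should have lesion-positive centres, recounted
    against the truth masks."""
    cases = _tiny_cases()
    n = 10_000
    rois = sample_rois(cases, n_total=n, tumor_fraction=0.5, seed=2)
    by_id = {c.case_id: c for c in cases}
    positives = sum(
        bool(by_id[cid].truth.data[x, y, z]) for (cid, z, x, y) in rois.provenance
    )
    assert 0.49 <= positives / n <= 0.51


def test_label_tile_is_truth_crop():
    cases = _tiny_cases()
    rois = sample_rois(cases, n_total=20, tile_size=10, seed=3)
    by_id = {c.case_id: c for c in cases}
    off = (10 - 1) // 2
    for i, (cid, z, x, y) in enumerate(rois.provenance):
        truth = by_id[cid].truth.data[:, :, z]
        if off <= x < truth.shape[0] - (10 - off) and off <= y < truth.shape[1] - (10 - off):
            crop = truth[x - off : x - off + 10, y - off : y - off + 10]
            assert np.array_equal(rois.labels[i].astype(bool), crop)


def test_no_lesions_with_positive_fraction_rejected():
    cases = _tiny_cases(n_lesions=0)
    with pytest.raises(NoPositiveTilesError):
        sample_rois(cases, n_total=10, tumor_fraction=0.5, seed=0)


def test_quota_shifts_from_lesion_free_cases():
    cases = _tiny_cases() + _tiny_cases(n_lesions=0)
    rois = sample_rois(cases, n_total=200, tumor_fraction=1.0, seed=4)
    assert len(rois) == 200


# --------------------------------------------------------------------------
# training and inference
# --------------------------------------------------------------------------

def test_one_epoch_records_one_history_entry():
    cases = _tiny_cases()
    rois = sample_rois(cases, n_total=32, seed=0)
    m = build_model(ModelConfig(), seed=0)
    train_model(m, rois, epochs=1, seed=0)
    assert len(m.training_history) == 1


def test_loss_floor_on_unanimous_background():
    """A model predicting background with probability -> 1 has loss -> 0."""
    from flairseg.nn import softmax_xent_grad

    prob = np.zeros((4, 8, 8, 2), dtype=np.float32)
    prob[..., 0] = 1 - 1e-7
    prob[..., 1] = 1e-7
    labels = np.zeros((4, 8, 8), dtype=np.uint8)
    loss, _ = softmax_xent_grad(prob, labels, np.ones_like(labels, dtype=np.float32))
    assert loss < 1e-5


def test_training_reduces_loss_by_half(e2e_result):
    """The reference 30-epoch run cuts training loss by >= 50% from epoch 1."""
    hist = e2e_result.model.training_history
    assert len(hist) == 30
    assert hist[-1] <= 0.5 * hist[0]


def test_training_deterministic():
    cases = _tiny_cases()
    rois = sample_rois(cases, n_total=64, seed=0)
    outs = []
    x = np.linspace(-1, 1, 2 * 16 * 16).reshape(2, 16, 16).astype(np.float32)
    for _ in range(2):
        m = build_model(ModelConfig(), seed=3)
        train_model(m, rois, epochs=2, seed=4)
        outs.append(m.forward(x))
    assert np.array_equal(outs[0], outs[1])


def test_predict_volume_contracts(e2e_result):
    model = e2e_result.model
    case = e2e_result.cohort.test[0]
    prob = predict_volume(model, case.volume)
    assert prob.data.shape == case.volume.data.shape
    assert prob.data.min() >= 0 and prob.data.max() <= 1


def test_prediction_separates_lesion_from_background(e2e_result):
    model = e2e_result.model
    case = e2e_result.cohort.test[0]
    prob = predict_volume(model, case.volume)
    inside = prob.data[case.truth.data].mean()
    outside = prob.data[~case.truth.data].mean()
    assert inside > outside


def test_untrained_model_rejected():
    m = build_model(ModelConfig(), seed=0)
    vol, _ = generate_phantom(
        PhantomSpec(shape=(16, 16, 8), n_lesions=0, lesion_radius_range=(2.0, 3.0), seed=0)
    )
    with pytest.raises(UntrainedModelError):
        predict_volume(m, vol)


def test_model_save_load_round_trip(tmp_path):
    cases = _tiny_cases()
    rois = sample_rois(cases, n_total=32, seed=0)
    m = build_model(ModelConfig(), seed=1)
    train_model(m, rois, epochs=1, seed=1)
    save_model(m, tmp_path / "model")
    back = load_model(tmp_path / "model")
    x = np.linspace(0, 1, 16 * 16).reshape(1, 16, 16).astype(np.float32)
    assert np.array_equal(m.forward(x), back.forward(x))
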