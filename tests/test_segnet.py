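"""Architecture contracts, gradient correctness, training behaviour."""

import numpy as np
import pytest

from coloqc import segnet
from coloqc.annotator import GRAY_CODE
from coloqc.color_features import RegionClass
from coloqc.segnet import SegNet, SegNetConfig, build_model, labels_from_gray, train


def _tiny_cfg(**kw):
    base = dict(input_height=16, input_width=16, base_channels=4,
                batch_size=2, schedule=((3, 1e-2),), seed=0)
    base.update(kw)
    return SegNetConfig(**base)


def _encode(labels):
    lut = np.zeros(256, dtype=np.uint8)
    for c, g in GRAY_CODE.items():
        lut[int(c)] = g
    return lut[labels]


def test_output_shape_contract(rng):
    cfg = SegNetConfig(input_height=64, input_width=64, base_channels=8,
                       batch_size=1, schedule=((1, 1e-3),), seed=0)
    model = build_model(cfg)
    frame = rng.integers(0, 256, (64, 64, 3)).astype(np.uint8)
    logits = model.forward(model._prepare(frame))
    assert logits.shape == (1, 64, 64, 4)


def test_untrained_model_labels_everything(rng):
    model = build_model(_tiny_cfg())
    out = model.predict(rng.integers(0, 256, (16, 16, 3)).astype(np.uint8))
    assert out.shape == (16, 16)
    assert set(np.unique(out)) <= {0, 1, 2, 3}
    assert int(RegionClass.UNCLASSIFIED) not in np.unique(out)


def test_parameter_count_matches_arithmetic():
    """Layer-by-layer sum for base 8: conv 3->8, 8->16, 16->8, 8->8 (3x3,
    bias, BN scale+shift each) plus the 1x1 four-class head."""
    cfg = _tiny_cfg(base_channels=8)
    expected = (
        (9 * 3 * 8 + 8 + 16)
        + (9 * 8 * 16 + 16 + 32)
        + (9 * 16 * 8 + 8 + 16)
        + (9 * 8 * 8 + 8 + 16)
        + (8 * 4 + 4)
    )
    assert segnet.param_count(cfg) == expected
    assert build_model(cfg).n_params == expected


def test_input_dims_must_divide_by_four():
    with pytest.raises(ValueError, match="divisible by 4"):
        SegNetConfig(input_height=30, input_width=64)


def test_gradients_match_finite_differences(rng):
    """Analytic backprop agrees with central differences (float64)."""
    model = build_model(_tiny_cfg(input_height=8, input_width=8, base_channels=3))
    for k in model.params:
        model.params[k] = model.params[k].astype(np.float64)
    for k in model.buffers:
        model.buffers[k] = model.buffers[k].astype(np.float64)
    x = rng.standard_normal((2, 8, 8, 3))
    y = rng.integers(0, 4, (2, 8, 8))
    y[0, 0, 0] = -1  # ignored pixel

    logits, cache = model.forward(x, want_cache=True, train=True)
    _, _, dlog = segnet._softmax_ce(logits, y)
    grads = model._backward(dlog, cache)

    eps = 1e-6
    for k in ("W1", "g2", "e3", "W4", "W5", "b5"):
        flat = model.params[k].ravel()
        for idx in rng.choice(flat.size, size=3, replace=False):
            old = flat[idx]
            flat[idx] = old + eps
            lp, _, _ = segnet._softmax_ce(model.forward(x, train=True), y)
            flat[idx] = old - eps
            lm, _, _ = segnet._softmax_ce(model.forward(x, train=True), y)
            flat[idx] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[k].ravel()[idx]
            assert abs(num - ana) <= 1e-5 * max(1.0, abs(num))


def test_labels_from_gray_rejects_foreign_levels():
    with pytest.raises(ValueError, match="77"):
        labels_from_gray(np.full((2, 2), 77, dtype=np.uint8))
    mapped = labels_from_gray(np.array([[0, 64], [94, 154]], dtype=np.uint8))
    assert mapped.tolist() == [[-1, 0], [1, 3]]


def test_default_schedule_totals_150_epochs():
    cfg = SegNetConfig()
    assert sum(e for e, _ in cfg.schedule) == 150
    assert [lr for _, lr in cfg.schedule] == [1e-3, 7e-4, 49e-5]
    assert cfg.batch_size == 48


def test_memorizes_single_pair_and_loss_decreases():
    """Training on one color-coded scene: the first-stage loss decreases and
    the model reproduces its annotation on labeled pixels."""
    from coloqc.synthetic import RegionPalette, SceneSpec, generate_frame

    spec = SceneSpec(height=32, width=32, seed=21)
    frame, labels = generate_frame(spec, RegionPalette())
    labels = labels.copy()
    labels[:3, :3] = int(RegionClass.UNCLASSIFIED)
    cfg = _tiny_cfg(input_height=32, input_width=32, base_channels=12,
                    batch_size=1, schedule=((120, 2e-2),))
    model = build_model(cfg)
    report = train(model, [frame], [_encode(labels)], cfg)
    losses = [h["loss"] for h in report.history]
    assert losses[-1] < losses[0]
    assert report.final_loss >= 0
    assert 0 <= report.final_accuracy <= 1
    pred = model.predict(frame)
    labeled = labels != int(RegionClass.UNCLASSIFIED)
    assert (pred[labeled] == labels[labeled]).mean() >= 0.99


def test_training_is_seed_reproducible(rng):
    frame = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    labels = _encode(rng.integers(0, 4, (16, 16)).astype(np.uint8))
    outs = []
    for _ in range(2):
        cfg = _tiny_cfg(schedule=((5, 1e-2),), seed=7)
        model = build_model(cfg)
        train(model, [frame], [labels], cfg)
        outs.append({k: v.copy() for k, v in model.params.items()})
    for k in outs[0]:
        assert np.array_equal(outs[0][k], outs[1][k])


def test_inference_is_deterministic(rng):
    model = build_model(_tiny_cfg())
    frame = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    assert np.array_equal(model.predict(frame), model.predict(frame))


def test_checkpoint_roundtrip(tmp_path, rng):
    cfg = _tiny_cfg(schedule=((2, 1e-2),))
    model = build_model(cfg)
    frame = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    labels = _encode(rng.integers(0, 4, (16, 16)).astype(np.uint8))
    train(model, [frame], [labels], cfg)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = SegNet.load(path)
    assert np.array_equal(loaded.predict(frame), model.predict(frame))
    assert loaded.cfg == cfg


def test_size_mismatch_rejected(rng):
    model = build_model(_tiny_cfg())
    with pytest.raises(ValueError, match="does not match"):
        model.predict(rng.integers(0, 256, (32, 32, 3)).astype(np.uint8))


def test_training_aborts_on_bad_labels(rng):
    model = build_model(_tiny_cfg())
    frame = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
    bad = np.full((16, 16), 33, dtype=np.uint8)
    with pytest.raises(ValueError, match="33"):
        train(model, [frame], [bad], model.cfg)
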