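"""Model contracts: shapes, architecture structure, loss values, training smoke."""

import numpy as np
import pytest

from ctrkit.errors import DataError, ParameterError
from ctrkit.models import (
    ARCHITECTURES,
    ModelConfig,
    TrainConfig,
    build_model,
    count_parameters,
    load_model,
    loss_dice_bce,
    predict_masks,
    save_model,
    train,
)
from ctrkit.phantom import CTRDistribution, generate_cohort


@pytest.mark.parametrize("arch", ARCHITECTURES)
def test_forward_preserves_spatial_size(arch):
    model = build_model(ModelConfig(architecture=arch, base_channels=4, depth=3, in_size=32))
    x = np.random.default_rng(0).normal(size=(2, 1, 32, 32)).astype(np.float32)
    logits = model.forward(x)
    assert logits.shape == (2, 2, 32, 32)


def test_invalid_configs_rejected():
    with pytest.raises(ParameterError):
        build_model(ModelConfig(architecture="resnet50"))
    with pytest.raises(ParameterError):
        build_model(ModelConfig(in_size=100, depth=3))  # 100 not divisible by 8
    with pytest.raises(ParameterError):
        build_model(ModelConfig(depth=1))


def test_segnet_has_unpooling_and_no_skip_concats():
    model = build_model(ModelConfig(architecture="segnet", base_channels=4, depth=2, in_size=16))
    assert hasattr(model, "unpools") and len(model.unpools) == 2
    assert not hasattr(model, "ups")
    unet = build_model(ModelConfig(architecture="vgg11_unet", base_channels=4, depth=2, in_size=16))
    assert hasattr(unet, "ups") and not hasattr(unet, "unpools")


def test_architectures_have_distinct_parameter_counts():
    counts = {
        arch: count_parameters(
            build_model(ModelConfig(architecture=arch, base_channels=8, depth=3, in_size=32))
        )
        for arch in ARCHITECTURES
    }
    assert len(set(counts.values())) == len(ARCHITECTURES), counts


# -- loss -------------------------------------------------------------------

def test_loss_perfect_prediction_reaches_bce_floor():
    t = np.zeros((1, 1, 8, 8))
    t[..., :4] = 1.0  # half ones
    logits = np.where(t > 0, 40.0, -40.0)
    loss = loss_dice_bce(logits, t)
    assert loss == pytest.approx(0.0, abs=1e-6)  # Dice -> 0, BCE at its floor


def test_loss_uniform_half_probability_closed_form():
    n = 16 * 16
    t = np.ones((1, 1, 16, 16))
    logits = np.zeros_like(t)  # p = 0.5 everywhere
    eps = 1.0
    expected_dice = 1 - (2 * 0.5 * n + eps) / (0.5 * n + n + eps)
    expected = expected_dice + np.log(2.0)
    assert loss_dice_bce(logits, t) == pytest.approx(expected, abs=1e-9)


def test_loss_matches_reference_expression_on_random_grids(rng):
    from scipy.special import expit
    for _ in range(10):
        z = rng.normal(size=(6, 7))
        t = (rng.random((6, 7)) > 0.5).astype(float)
        p = expit(z)
        dice = 1 - (2 * np.sum(p * t) + 1.0) / (np.sum(p) + np.sum(t) + 1.0)
        bce = np.mean(-t * np.log(p) - (1 - t) * np.log(1 - p))
        assert loss_dice_bce(z, t) == pytest.approx(dice + bce, abs=1e-6)


def test_dice_term_bounded_loss_finite(rng):
    z = rng.normal(scale=30, size=(2, 2, 8, 8))
    t = (rng.random((2, 2, 8, 8)) > 0.5).astype(float)
    assert np.isfinite(loss_dice_bce(z, t))


# -- training ---------------------------------------------------------------

@pytest.fixture(scope="module")
def mini_cohort():
    return generate_cohort(
        16, CTRDistribution.normal(0.5, 0.05, 0.4, 0.6), seed=8, image_size=64
    )


def test_training_reduces_loss_and_is_seed_deterministic(mini_cohort):
    cfg = ModelConfig(architecture="albunet", base_channels=4, depth=2, in_size=64)
    tcfg = TrainConfig(batch_size=4, epochs=3, learning_rate=1e-3, seed=3)
    _, trace1 = train(build_model(cfg, seed=0), mini_cohort, tcfg)
    _, trace2 = train(build_model(cfg, seed=0), mini_cohort, tcfg)
    assert trace1 == trace2  # identical seeds, identical traces
    assert trace1[-1] < trace1[0]


def test_empty_cohort_rejected():
    model = build_model(ModelConfig(base_channels=4, depth=2, in_size=32))
    with pytest.raises(DataError):
        train(model, [], TrainConfig())


def test_untrained_model_degenerates_gracefully(mini_cohort):
    """Untrained masks may be empty; downstream grading must see poor, not crash."""
    from ctrkit.assist import grade_single
    from ctrkit.geometry import clean_mask

    model = build_model(ModelConfig(base_channels=4, depth=2, in_size=64), seed=0)
    lung, heart = predict_masks(model, mini_cohort[0].image)
    lung = clean_mask(lung, keep_components=2)
    heart = clean_mask(heart, keep_components=1)
    grade = grade_single(None, 0.5) if not (lung.any() and heart.any()) else "measurable"
    assert grade in ("poor", "measurable")


def test_full_frame_prediction_when_all_above_threshold(mini_cohort):
    model = build_model(ModelConfig(base_channels=4, depth=2, in_size=64), seed=0)
    for p in model.params():  # force hugely positive logits via the head bias
        p["value"][...] = 0.0
    model.head.b[...] = 50.0
    lung, heart = predict_masks(model, mini_cohort[0].image)
    assert lung.all() and heart.all()


def test_checkpoint_roundtrip(tmp_path, mini_cohort):
    cfg = ModelConfig(architecture="segnet", base_channels=4, depth=2, in_size=64)
    model, _ = train(
        build_model(cfg, seed=1), mini_cohort,
        TrainConfig(batch_size=4, epochs=1, learning_rate=1e-3, seed=0),
    )
    path = tmp_path / "ckpt.npz"
    save_model(model, path)
    restored = load_model(path)
    assert restored.config == cfg
    x = mini_cohort[0].image
    np.testing.assert_array_equal(
        predict_masks(model, x)[0], predict_masks(restored, x)[0]
    )


def test_full_scale_train_config_defaults():
    cfg = TrainConfig()
    assert cfg.batch_size == 8 and cfg.epochs == 75 and cfg.learning_rate == 1e-4
    assert cfg.optimizer == "adam" and cfg.loss == "dice_plus_bce"
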