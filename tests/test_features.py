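"""Conv trunk correctness and receptive-field accounting."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from perceptgap.features import (FeatureTrunk, GENERIC_PLAN, LOCAL_PLAN,
                                 LayerSpec, analytic_receptive_field,
                                 conv_relu, measure_receptive_field,
                                 normalize_image, random_conv_plan)


def test_conv_relu_matches_scipy_oracle():
    """Valid conv + relu agrees with scipy.signal.correlate2d."""
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, (1, 2, 12, 12)).astype(np.float32)
    w = rng.normal(0, 1, (3, 2, 3, 3)).astype(np.float32)
    out = conv_relu(x, w, stride=1)
    for o in range(3):
        ref = sum(correlate2d(x[0, c], w[o, c], mode="valid")
                  for c in range(2))
        ref = np.maximum(ref, 0)
        assert np.allclose(out[0, o], ref, atol=1e-4)


def test_strided_conv_subsamples():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, (1, 1, 11, 11)).astype(np.float32)
    w = rng.normal(0, 1, (1, 1, 3, 3)).astype(np.float32)
    full = conv_relu(x, w, stride=1)
    s2 = conv_relu(x, w, stride=2)
    assert np.allclose(s2[0, 0], full[0, 0, ::2, ::2])


def test_analytic_receptive_field_values():
    assert analytic_receptive_field(LOCAL_PLAN) == (33, 8)
    assert analytic_receptive_field(GENERIC_PLAN)[0] == 145
    # k stacked 3x3 stride-1 stages: closed form 2k+1
    for k in range(1, 5):
        assert analytic_receptive_field(random_conv_plan(k))[0] == 2 * k + 1


@pytest.mark.parametrize("k", [1, 2, 3])
def test_measured_rf_matches_closed_form_for_plain_stacks(k):
    """Empirical single-pixel probe equals the analytic 2k+1 bound."""
    trunk = FeatureTrunk(random_conv_plan(k, channels=4))
    assert measure_receptive_field(trunk) == 2 * k + 1


def test_pointwise_model_has_rf_one():
    trunk = FeatureTrunk((LayerSpec(1, 1, 4, "random"),))
    assert measure_receptive_field(trunk) == 1


def test_empirical_rf_never_exceeds_analytic_bound():
    plan = (LayerSpec(3, 2, 4, "random"), LayerSpec(3, 1, 4, "random"))
    trunk = FeatureTrunk(plan)
    assert measure_receptive_field(trunk) <= analytic_receptive_field(plan)[0]


def test_trunk_forward_shapes_and_determinism():
    trunk = FeatureTrunk(LOCAL_PLAN)
    img = np.random.default_rng(2).integers(0, 255, (256, 256)).astype(np.uint8)
    m1 = trunk.features(img)
    m2 = trunk.features(img)
    assert m1[6].shape == (96, 28, 28)
    assert np.array_equal(m1[6], m2[6])
    # patch grid count matches the stride-8 tiling of 33-px windows
    assert m1[6].shape[-1] == (256 - 33) // 8 + 1


def test_uniform_background_gives_zero_features():
    """First-layer filters are zero-mean: constant input -> zero response."""
    trunk = FeatureTrunk(LOCAL_PLAN)
    img = np.full((128, 128), 128, np.uint8)
    assert np.abs(trunk.features(img)[6]).max() < 1e-5


def test_normalize_image_range():
    x = normalize_image(np.array([[0, 128, 255]], dtype=np.uint8))
    assert x[0, 0] == pytest.approx(-1.0)
    assert abs(x[0, 1]) < 0.01
    assert x[0, 2] == pytest.approx(1.0)


def test_unknown_recipe_rejected():
    with pytest.raises(ValueError):
        FeatureTrunk((LayerSpec(3, 1, 4, "bogus"),))
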