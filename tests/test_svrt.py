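"""Abstract-rule task generators and the learning-curve harness."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from perceptgap.svrt_tasks import (TASKS, TaskSpec, generate_task,
                                   learning_curve, recompute_label)


def test_task_registry_categories():
    assert TASKS["inside_outside"] == "spatial"
    assert TASKS["left_of_right_of"] == "spatial"
    assert TASKS["same_different_translation"] == "same_different"
    assert TASKS["same_different_scaled"] == "same_different"
    with pytest.raises(ValueError):
        generate_task("count_shapes", 4)


@pytest.mark.parametrize("task_id", list(TASKS))
def test_labels_recomputable_and_balanced(task_id):
    """Every label is reproducible from the stored outline geometry."""
    recs = generate_task(task_id, 2500, seed=17, render_images=False)
    assert all(recompute_label(r) == r.label for r in recs)
    ys = [r.y for r in recs]
    assert sum(ys) == 1250                      # exact balance


def test_same_pairs_identical_after_alignment():
    recs = generate_task("same_different_translation", 40, seed=5,
                         render_images=False)
    for r in recs:
        a, b = (s.outline.vertices for s in r.shapes)
        aligned = np.allclose(a - a.min(axis=0), b - b.min(axis=0), atol=1e-8)
        assert aligned == (r.label == "same")


def test_inside_label_means_containment():
    recs = generate_task("inside_outside", 40, seed=6, render_images=False)
    for r in recs:
        big = Polygon(r.shapes[0].outline.vertices)
        small = Polygon(r.shapes[1].outline.vertices)
        assert big.contains(small) == (r.label == "inside")
        if r.label == "outside":
            assert big.distance(small) > 0


def test_outlines_are_simple_and_closed():
    for task_id in TASKS:
        recs = generate_task(task_id, 20, seed=8, render_images=False)
        for r in recs:
            for s in r.shapes:
                assert s.outline.closed and s.outline.is_simple()


def test_rendered_images_have_expected_size():
    recs = generate_task("inside_outside", 4, seed=9)
    assert all(r.image.shape == (128, 128) for r in recs)
    recs256 = generate_task(TaskSpec("inside_outside", image_size=256), 4,
                            seed=9)
    assert all(r.image.shape == (256, 256) for r in recs256)


def test_generation_determinism():
    a = generate_task("left_of_right_of", 10, seed=4)
    b = generate_task("left_of_right_of", 10, seed=4)
    assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))


def test_learning_curve_oracle_and_chance(oracle_model, constant_model):
    """An oracle reaches 1.0 at every size; a constant model stays at 0.5."""
    lc = learning_curve(lambda seed: oracle_model,
                        ["inside_outside"], [20, 40], seed=1, n_test=40)
    assert np.allclose(lc["accuracy"], 1.0)
    assert set(lc["train_size"]) == {20, 40}
    lc_c = learning_curve(lambda seed: constant_model,
                          ["left_of_right_of"], [20], seed=1, n_test=40)
    assert np.allclose(lc_c["accuracy"], 0.5)


def test_learning_curve_table_shape(oracle_model):
    lc = learning_curve(lambda seed: oracle_model, list(TASKS), [16],
                        seed=0, n_test=16)
    assert len(lc) == len(TASKS)
    assert set(lc["category"]) == {"spatial", "same_different"}
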