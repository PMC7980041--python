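"""Patch-evidence decomposition and extreme-patch selection."""

import itertools

import numpy as np
import pytest

from perceptgap.classifiers import records_to_arrays
from perceptgap.evidence_heatmap import (PatchLogitMap,
                                         endpoint_evidence_report,
                                         extract_extreme_patches,
                                         patch_logit_map)


def test_pooling_consistency(local_model, test_records):
    """Spatial mean of the patch-logit grid reproduces the image logit."""
    X, _ = records_to_arrays(test_records[:30])
    logits = local_model.decision_function(X)
    for img, logit in zip(X, logits):
        pmap = patch_logit_map(local_model, img)
        assert abs(pmap.pooled_logit - logit) < 1e-5


def test_uniform_background_gives_constant_grid(local_model):
    img = np.full((256, 256), 128, np.uint8)
    pmap = patch_logit_map(local_model, img)
    assert pmap.grid.shape == (28, 28)
    assert np.ptp(pmap.grid) < 1e-5


def test_generic_model_has_no_patch_grid(generic_model):
    img = np.full((128, 128), 128, np.uint8)
    with pytest.raises(TypeError, match="receptive field"):
        patch_logit_map(generic_model, img)


def test_patch_rect_geometry(local_model):
    pmap = patch_logit_map(local_model, np.full((256, 256), 128, np.uint8))
    assert pmap.patch_size == 33 and pmap.stride == 8
    assert pmap.patch_rect(0, 0) == (0, 0, 33, 33)
    assert pmap.patch_rect(2, 1) == (8, 16, 41, 49)


# ---------------------------------------------------------------------------
# Greedy extreme-patch selection
# ---------------------------------------------------------------------------

def _pmap(grid, patch_cells=3, stride=8):
    return PatchLogitMap(grid=np.asarray(grid, float),
                         patch_size=patch_cells * stride, stride=stride)


def test_single_nonzero_cell():
    g = np.zeros((6, 6))
    g[2, 3] = -1.5
    res = extract_extreme_patches(_pmap(g), k=3)
    assert len(res) >= 1
    assert res.patches[0].cell == (2, 3)
    assert res.patches[0].logit == -1.5


def test_two_separated_peaks_both_selected():
    g = np.zeros((6, 6))
    g[0, 0] = 2.0
    g[5, 5] = -1.0
    res = extract_extreme_patches(_pmap(g), k=2)
    cells = {p.cell for p in res.patches}
    assert cells == {(0, 0), (5, 5)}
    assert res.patches[0].logit == 2.0          # sorted by |logit|


def test_k_validation_and_crops():
    g = np.ones((4, 4))
    with pytest.raises(ValueError):
        extract_extreme_patches(_pmap(g), k=0)
    img = (np.arange(64 * 64).reshape(64, 64) % 256).astype(np.uint8)
    res = extract_extreme_patches(_pmap(g, patch_cells=2), k=1, image=img)
    p = res.patches[0]
    assert p.crop.shape == (16, 16)
    x0, y0 = p.top_left
    assert np.array_equal(p.crop, img[y0:y0 + 16, x0:x0 + 16])


def _overlaps(a, b, size):
    return (abs(a[0] - b[0]) < size) and (abs(a[1] - b[1]) < size)


def test_returned_sets_never_overlap():
    rng = np.random.default_rng(0)
    for _ in range(50):
        g = rng.normal(size=(8, 8))
        res = extract_extreme_patches(_pmap(g), k=4)
        cells = [p.cell for p in res.patches]
        for a, b in itertools.combinations(cells, 2):
            assert not _overlaps(a, b, 3)       # 3-cell footprint


def test_greedy_matches_pair_enumeration_oracle():
    """For k=2 on random 8x8 maps with a 3-cell footprint, greedy total
    |logit| never exceeds the exhaustive-pair optimum and matches it in at
    least 95% of 1000 maps."""
    rng = np.random.default_rng(7)
    cells = list(itertools.product(range(8), range(8)))
    valid_pairs = [(a, b) for a, b in itertools.combinations(cells, 2)
                   if not _overlaps(a, b, 3)]
    match = 0
    for _ in range(1000):
        g = rng.normal(size=(8, 8))
        res = extract_extreme_patches(_pmap(g), k=2)
        got = sum(abs(p.logit) for p in res.patches)
        best = max(abs(g[a]) + abs(g[b]) for a, b in valid_pairs)
        assert got <= best + 1e-12
        if abs(got - best) < 1e-12:
            match += 1
    assert match >= 950


def test_open_stimuli_attract_more_positive_evidence(local_model,
                                                     test_records):
    """Aggregated over ~100 stimuli per class, open stimuli have more
    positive-logit (open-evidence) patches than closed stimuli."""
    pos = {"open": [], "closed": []}
    for r in test_records:
        n_pos = int((local_model.patch_logit_grid(r.image) > 0).sum())
        pos[r.label].append(n_pos)
    assert min(len(pos["open"]), len(pos["closed"])) >= 90
    mean_open = np.mean(pos["open"])
    mean_closed = np.mean(pos["closed"])
    print(f"\n[evidence] mean positive patches: open {mean_open:.1f} "
          f"closed {mean_closed:.1f}")
    assert mean_open > mean_closed


def test_endpoint_evidence_report_schema(local_model, test_records):
    rep = endpoint_evidence_report(local_model, test_records[:20],
                                   n_permutations=50, seed=0)
    assert 0 <= rep["observed_rate"] <= 1
    assert 0 < rep["p_value"] <= 1
    assert rep["n_stimuli"] == sum(r.label == "open" for r in test_records[:20])
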