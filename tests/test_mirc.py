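"""MIRC search: expansion rules, descent, gap statistics."""

import numpy as np
import pytest

from perceptgap.mirc_search import (GapStats, MircResult, SearchNode,
                                    SearchParams, aggregate_gaps, descend,
                                    expand_children, node_image,
                                    recognition_gap)


# ---------------------------------------------------------------------------
# Recognition-gap arithmetic
# ---------------------------------------------------------------------------

def test_gap_worked_examples():
    assert recognition_gap(0.9, [0.2]) == pytest.approx(0.7)
    assert recognition_gap(0.9999, [0.0002]) == pytest.approx(0.9997)


def test_gap_uses_best_child_and_identity():
    assert recognition_gap(0.8, [0.1, 0.45, 0.3]) == pytest.approx(0.35)
    assert recognition_gap(0.6, [0.6]) == 0.0
    with pytest.raises(ValueError):
        recognition_gap(0.9, [])


# ---------------------------------------------------------------------------
# Expansion
# ---------------------------------------------------------------------------

def test_expansion_count_and_kinds():
    node = SearchNode(rect=(0, 0, 100, 100))
    ch = expand_children(node, SearchParams())
    assert len(ch) == 6
    assert [c.kind for c in ch] == ["crop_tl", "crop_tr", "crop_bl",
                                    "crop_br", "crop_c", "resolution"]
    crops = ch[:5]
    assert all(c.width == 80 and c.height == 80 for c in crops)
    assert ch[5].rect == node.rect and ch[5].scale == pytest.approx(0.8)


def test_expansion_floor_is_empty():
    node = SearchNode(rect=(0, 0, 34, 34), scale=1.0)
    # crop child would be 27 px < 33; resolution child 27.2 effective px
    assert expand_children(node, SearchParams()) == []


def test_children_contained_in_parent():
    rng = np.random.default_rng(0)
    params = SearchParams(min_size=8)
    for _ in range(1000):
        x0, y0 = rng.integers(0, 100, 2)
        w = int(rng.integers(20, 150))
        node = SearchNode(rect=(int(x0), int(y0), int(x0 + w), int(y0 + w)),
                          scale=float(rng.uniform(0.3, 1.0)))
        for c in expand_children(node, params):
            assert c.rect[0] >= node.rect[0] and c.rect[1] >= node.rect[1]
            assert c.rect[2] <= node.rect[2] and c.rect[3] <= node.rect[3]
            assert c.scale <= node.scale


def test_invalid_params_rejected():
    for kw in ({"crop_fraction": 1.0}, {"resolution_factor": 0.0},
               {"threshold": 1.0}):
        with pytest.raises(ValueError):
            SearchParams(**kw)


def test_node_image_crop_and_degradation():
    img = np.zeros((64, 64))
    img[20:30, 20:30] = 255
    crop = node_image(img, SearchNode(rect=(16, 16, 48, 48)))
    assert crop.shape == (32, 32)
    assert crop.max() == 255
    low = node_image(img, SearchNode(rect=(16, 16, 48, 48), scale=0.3))
    assert low.shape == (32, 32)
    assert low.max() < 255                      # resolution loss blurs


# ---------------------------------------------------------------------------
# Descent
# ---------------------------------------------------------------------------

def _step(s0):
    """Deterministic classifier recognizing any view with side >= s0."""
    return lambda view, node: 1.0 if node.side >= s0 else 0.0


def test_unrecognized_image_is_skipped():
    assert descend(lambda v, n: 0.4, np.zeros((64, 64))) is None


def test_ceiling_model_floor_flagged():
    res = descend(lambda v, n: 1.0, np.zeros((256, 256)))
    assert res.floor_flagged and res.sub_mircs == []
    assert np.isnan(res.gap)


def test_non_finite_probability_raises():
    with pytest.raises(ValueError):
        descend(lambda v, n: float("nan"), np.zeros((64, 64)))


def _oracle_tree_mircs(size, s0, params):
    """Independent enumeration of the full expansion tree.

    Re-derives the child geometry from the documented rules (corner/center
    crops at the rounded fraction, resolution child at scaled resolution,
    min-size floors) and collects every node satisfying the MIRC
    definition for a side-threshold classifier: p(side) >= threshold and
    all children < threshold.
    """
    f, r, m = params.crop_fraction, params.resolution_factor, params.min_size
    mircs = set()
    seen = set()

    def children_of(x0, y0, x1, y1, scale):
        w, h = x1 - x0, y1 - y0
        cw, ch = int(round(w * f)), int(round(h * f))
        out = []
        if min(cw, ch) >= m:
            for ax, ay in ((x0, y0), (x1 - cw, y0), (x0, y1 - ch),
                           (x1 - cw, y1 - ch),
                           (x0 + (w - cw) // 2, y0 + (h - ch) // 2)):
                out.append((ax, ay, ax + cw, ay + ch, scale))
        if min(w, h) * scale * r >= m:
            out.append((x0, y0, x1, y1, scale * r))
        return out

    def walk(state):
        if state in seen:
            return
        seen.add(state)
        x0, y0, x1, y1, scale = state
        side = min(x1 - x0, y1 - y0)
        kids = children_of(*state)
        if side >= s0 and kids and all(
                min(k[2] - k[0], k[3] - k[1]) < s0 for k in kids):
            mircs.add(state)
        for k in kids:
            walk(k)

    walk((0, 0, size, size, 1.0))
    return mircs


@pytest.mark.parametrize("s0", [12, 20, 34])
def test_descent_matches_brute_force_oracle(s0):
    """On 64-px images with a side-threshold classifier, the greedy MIRC
    is one of the nodes the exhaustive tree enumeration identifies as a
    MIRC, and the gap is exactly 1."""
    params = SearchParams(min_size=8)
    res = descend(_step(s0), np.zeros((64, 64)), params=params)
    oracle = _oracle_tree_mircs(64, s0, params)
    state = (*res.mirc.rect, res.mirc.scale)
    assert state in oracle
    assert res.gap == pytest.approx(1.0)
    assert res.mirc.side >= s0
    assert all(c.side < s0 for c in res.sub_mircs if "crop" in c.kind)


def test_structural_invariants_of_results():
    """gap > 0 and gap >= p_mirc - threshold; best-sub-MIRC gap is never
    larger than the worst-sub-MIRC gap (conservative definition)."""
    rng = np.random.default_rng(3)

    def noisy(v, node):
        # recognizable above 24 px with wobble, never crossing threshold
        base = 0.9 if node.side >= 24 else 0.2
        return float(np.clip(base + 0.08 * np.sin(node.rect[0] * 12.9898
                                                  + node.rect[1]), 0, 1))

    params = SearchParams(min_size=8)
    res = descend(noisy, np.zeros((64, 64)), params=params)
    assert res is not None and not res.floor_flagged
    ps = [c.p_correct for c in res.sub_mircs]
    assert res.gap > 0
    assert res.gap >= res.mirc.p_correct - params.threshold - 1e-12
    gap_best = res.mirc.p_correct - max(ps)
    gap_worst = res.mirc.p_correct - min(ps)
    assert gap_best <= gap_worst
    assert res.gap == pytest.approx(gap_best)


def test_descent_trace_is_deterministic():
    def pseudo(v, node):
        h = (hash(node.rect) % 997) / 997.0
        return 0.55 + 0.45 * h if node.side >= 20 else 0.1

    params = SearchParams(min_size=8)
    r1 = descend(pseudo, np.zeros((64, 64)), params=params)
    r2 = descend(pseudo, np.zeros((64, 64)), params=params)
    assert [(t.rect, t.scale, t.p_correct) for t in r1.trace] == \
           [(t.rect, t.scale, t.p_correct) for t in r2.trace]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _result(gap, floor=False):
    n = SearchNode(rect=(0, 0, 40, 40), p_correct=1.0)
    return MircResult(mirc=n, sub_mircs=[], gap=gap, trace=[n],
                      floor_flagged=floor)


def test_aggregate_hand_arithmetic():
    assert aggregate_gaps([_result(0.7)]) == GapStats(0.7, 0.0, 1, 0)
    s = aggregate_gaps([_result(0.6), _result(0.8)])
    assert s.mean == pytest.approx(0.7)
    assert s.sd == pytest.approx(0.1)
    assert s.n == 2


def test_aggregate_excludes_floor_flagged():
    s = aggregate_gaps([_result(0.5), _result(float("nan"), floor=True)])
    assert s.n == 1 and s.n_floor == 1 and s.mean == pytest.approx(0.5)
    with pytest.raises(ValueError):
        aggregate_gaps([])


def test_hundred_sharp_classifiers_give_unit_gaps():
    """100 side-threshold classifiers with varying thresholds all produce
    gap exactly 1 on a 64-px image."""
    params = SearchParams(min_size=8)
    results = [descend(_step(s0), np.zeros((64, 64)), params=params)
               for s0 in np.linspace(10, 40, 100)]
    stats = aggregate_gaps([r for r in results if r is not None])
    assert stats.mean == pytest.approx(1.0)
    assert stats.sd == pytest.approx(0.0)
    assert stats.n == 100
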