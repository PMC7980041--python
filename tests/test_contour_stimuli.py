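"""Generator contracts for the closed/open-contour training distribution."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from perceptgap.contour_stimuli import (FlankerSpec, GenerationError,
                                        GeneratorConfig, MainContourSpec,
                                        generate_dataset, label_from_geometry,
                                        sample_flankers, sample_main_contour)
from perceptgap.render import RenderConfig, line_mask


def test_minimal_closed_contour_is_a_triangle():
    rng = np.random.default_rng(0)
    p = sample_main_contour(MainContourSpec(3, closed=True), rng)
    assert p.closed and p.n_segments == 3 and p.is_simple()
    assert p.endpoint_separation == 0.0


def test_open_contour_gap_at_least_minimum():
    rng = np.random.default_rng(1)
    for _ in range(50):
        p = sample_main_contour(
            MainContourSpec(5, closed=False, open_gap_min=16.0), rng)
        assert not p.closed
        assert p.endpoint_separation >= 16.0
        assert p.is_simple()


def test_overconstrained_spec_raises():
    rng = np.random.default_rng(2)
    with pytest.raises(GenerationError):
        # cannot fit a 400-px contour into a 256-px canvas with margin
        sample_main_contour(
            MainContourSpec(5, closed=True, target_diameter=400.0), rng)


def test_segment_count_coverage_and_bounds(geometry_batch):
    """Over 10^4+ contours, segment counts cover exactly {3..9}."""
    counts = {r.main.n_segments for r in geometry_batch}
    assert counts == set(range(3, 10))


def test_label_recoverable_from_geometry(geometry_batch):
    """Closedness recomputed from stored vertices equals the stored label."""
    assert all(label_from_geometry(r.main) == r.label for r in geometry_batch)


def test_geometric_validity(geometry_batch):
    """No self-intersections; contours respect the canvas margin."""
    sample = geometry_batch[::7]
    assert all(r.main.is_simple() for r in sample)
    assert all(r.main.within_canvas(256, margin=15.99) for r in sample)


def test_class_statistics_match(geometry_batch):
    """Segment-count and arc-length distributions are indistinguishable
    between classes (two-sample rank test, alpha=0.01, 10^4 per class)."""
    closed = [r for r in geometry_batch if r.label == "closed"]
    opened = [r for r in geometry_batch if r.label == "open"]
    assert min(len(closed), len(opened)) >= 10_000
    for attr in (lambda r: r.main.n_segments, lambda r: r.main.length):
        a = [attr(r) for r in closed]
        b = [attr(r) for r in opened]
        p = mannwhitneyu(a, b).pvalue
        assert p > 0.01, f"distributions differ (p={p:.2e})"


def test_flanker_lengths_and_counts():
    rng = np.random.default_rng(3)
    spec = FlankerSpec()
    n_seen = 0
    while n_seen < 2000:
        fl = sample_flankers(spec, None, rng)
        for f in fl:
            assert not f.closed
            assert f.n_segments in (1, 2)
            assert f.segment_lengths().min() >= 32.0
            n_seen += 1
    assert sample_flankers(FlankerSpec(count_range=(0, 0)), None, rng) == []


def test_flankers_never_touch_main_contour():
    """Rasterized flanker pixels never overlap main-contour pixels."""
    cfg = RenderConfig(antialias=False)
    recs, _ = generate_dataset(60, 0.5, seed=44, render_images=False)
    for r in recs:
        main_mask = line_mask([r.main], cfg, threshold=0.0)
        if r.flankers:
            fl_mask = line_mask(r.flankers, cfg, threshold=0.0)
            assert not np.any(main_mask & fl_mask)


def test_dataset_balance_and_shapes():
    recs, manifest = generate_dataset(100, 0.5, seed=7)
    labels = manifest["label"].value_counts()
    assert labels["closed"] == 50 and labels["open"] == 50
    assert all(r.image.shape == (256, 256) for r in recs)
    with pytest.raises(ValueError):
        generate_dataset(1)


def test_seed_determinism_bytes():
    a, ma = generate_dataset(12, 0.5, seed=99)
    b, mb = generate_dataset(12, 0.5, seed=99)
    assert all(np.array_equal(x.image, y.image) for x, y in zip(a, b))
    assert ma.equals(mb)
    c, _ = generate_dataset(12, 0.5, seed=100)
    assert any(not np.array_equal(x.image, y.image) for x, y in zip(a, c))


def test_record_metadata_roundtrip():
    recs, _ = generate_dataset(4, 0.5, seed=5, render_images=False)
    md = recs[0].to_metadata()
    assert md["label"] == recs[0].label
    assert len(md["main"]["vertices"]) == len(recs[0].main.vertices)
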