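"""Convolutional feature trunks with exact receptive-field accounting.

The two model families share a feed-forward convolutional feature
hierarchy built from fixed filters: oriented line detectors at the first
layer, hand-designed line-termination ("endpoint") detectors at a middle
layer, and random projections elsewhere.  Only the readout on top of the
trunk is trained (see :mod:`perceptgap.classifiers`), which keeps training
CPU-cheap and fully deterministic while preserving the property the
analyses rely on: every unit of the top convolutional layer sees a
precisely bounded input region.

The *local* plan stops at an analytic receptive field of exactly 33x33
pixels with a native stride of 8 — the patch grid on which per-patch
evidence is defined.  The *generic* plan continues with further strided
layers to a receptive field an order of magnitude larger.

Receptive fields can be measured empirically by single-pixel perturbation
probing (:func:`measure_receptive_field`), which is how the 33-px bound is
verified rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LayerSpec", "FeatureTrunk", "LOCAL_PLAN", "GENERIC_PLAN",
    "analytic_receptive_field", "measure_receptive_field", "normalize_image",
    "random_conv_plan",
]

N_ORIENT = 8          # orientation channels in [0, pi)
_ENDPOINT_SLICE = slice(8, 24)   # the 16 directed endpoint channels at layer 3


@dataclass(frozen=True)
class LayerSpec:
    """One convolution stage: kernel size, stride, width and filter recipe.

    ``init`` selects the filter recipe: ``oriented`` (line detectors),
    ``smooth`` (per-channel blur passthrough), ``endpoint`` (directed
    termination detectors + passthrough + random), ``pool_random`` (pooled
    endpointness + random) or ``random``.
    """

    kernel: int
    stride: int
    out_channels: int
    init: str = "random"


# Receptive field 33, jump 8 at the top (verified by test + probe):
# r: 7 -> 9 -> 13 -> 17 -> 25 -> 33
LOCAL_PLAN: tuple[LayerSpec, ...] = (
    LayerSpec(7, 1, N_ORIENT, "oriented"),
    LayerSpec(3, 2, 16, "smooth"),
    LayerSpec(3, 1, 32, "endpoint"),
    LayerSpec(3, 2, 32, "pool_random"),
    LayerSpec(3, 1, 48, "carry_random"),
    LayerSpec(3, 2, 96, "carry_random"),
)

_N_CARRY = 25      # designed channels carried to the top: tipness + 8 E + 16 EP

# Continues the local plan: r 33 -> 65 -> 81 -> 113 -> 145, jump 32.
GENERIC_PLAN: tuple[LayerSpec, ...] = LOCAL_PLAN + (
    LayerSpec(5, 1, 32, "random"),
    LayerSpec(3, 2, 32, "random"),
    LayerSpec(3, 1, 32, "random"),
    LayerSpec(3, 2, 32, "random"),
)


def random_conv_plan(n_layers: int, kernel: int = 3, stride: int = 1,
                     channels: int = 8) -> tuple[LayerSpec, ...]:
    """A plain stack of random conv stages (for receptive-field probes)."""
    return tuple(LayerSpec(kernel, stride, channels, "random")
                 for _ in range(n_layers))


def analytic_receptive_field(plan: Sequence[LayerSpec],
                             upto: int | None = None) -> tuple[int, int]:
    """Closed-form (receptive_field, jump) of layer ``upto`` (1-based)."""
    r, j = 1, 1
    for spec in list(plan)[: (upto if upto is not None else len(plan))]:
        r += (spec.kernel - 1) * j
        j *= spec.stride
    return r, j


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Map 8-bit gray to [-1, 1]; the mid-gray background maps near zero."""
    return (np.asarray(image, dtype=np.float32) / 255.0 - 0.5) * 2.0


# ---------------------------------------------------------------------------
# Filter construction
# ---------------------------------------------------------------------------

def _orientations() -> np.ndarray:
    return np.arange(N_ORIENT) * np.pi / N_ORIENT


def _oriented_bar_kernels(k: int) -> np.ndarray:
    """Oriented line detectors responding positively to *dark* lines.

    Elongated along the orientation with a center-surround cross-section
    matched to thin lines; zero-mean so uniform backgrounds give exactly
    zero response.
    """
    half = (k - 1) / 2.0
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    kernels = np.zeros((N_ORIENT, 1, k, k), dtype=np.float64)
    for i, th in enumerate(_orientations()):
        along = xx * np.cos(th) + yy * np.sin(th)
        cross = -xx * np.sin(th) + yy * np.cos(th)
        sc, sa = 1.2, 2.4
        g = (1.0 - (cross / sc) ** 2) * np.exp(
            -cross ** 2 / (2 * sc ** 2) - along ** 2 / (2 * sa ** 2))
        g -= g.mean()
        g /= np.linalg.norm(g)
        kernels[i, 0] = -g          # dark line (negative input) -> positive
    return kernels.astype(np.float32)


def _direction_offsets() -> list[tuple[int, int]]:
    """Rounded unit-step (dx, dy) for the 16 directions theta_i and theta_i+pi."""
    offs = []
    for th in _orientations():
        for d in (th, th + np.pi):
            offs.append((int(np.round(np.cos(d))), int(np.round(np.sin(d)))))
    return offs


def _rand_kernels(rng: np.random.Generator, out_c: int, in_c: int,
                  k: int) -> np.ndarray:
    w = rng.normal(0.0, 1.0, size=(out_c, in_c, k, k))
    w *= np.sqrt(2.0 / (in_c * k * k))
    return w.astype(np.float32)


def _build_weights(plan: Sequence[LayerSpec], seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFEA7]))
    weights = []
    in_c = 1
    for li, spec in enumerate(plan):
        k, out_c = spec.kernel, spec.out_channels
        if spec.init == "oriented":
            w = _oriented_bar_kernels(k)
            assert w.shape[0] == out_c
        elif spec.init == "smooth":
            # first N_ORIENT outputs: per-orientation 3x3 blur passthrough
            w = _rand_kernels(rng, out_c, in_c, k) * 0.7
            blur = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float32)
            blur /= blur.sum()
            w[:N_ORIENT] = 0.0
            for i in range(N_ORIENT):
                w[i, i] = blur
        elif spec.init == "endpoint":
            # outputs: [0:8] passthrough, [8:24] directed endpoint detectors,
            # [24:] random mixtures.  A detector fires where its orientation's
            # energy ends along the direction AND no competing orientation is
            # present — the competition term keeps polygon corners (where one
            # edge orientation hands over to another) from masquerading as
            # line endpoints.
            w = _rand_kernels(rng, out_c, in_c, k) * 0.7
            w[:24] = 0.0
            ident = np.zeros((k, k), dtype=np.float32)
            ident[k // 2, k // 2] = 1.0
            for i in range(N_ORIENT):
                w[i, i] = ident * 0.8
            gain = 2.0
            for d, (dx, dy) in enumerate(_direction_offsets()):
                i = d // 2                       # source orientation channel
                kk = np.zeros((k, k), dtype=np.float32)
                kk[k // 2, k // 2] = 1.0 * gain
                kk[k // 2 + dy, k // 2 + dx] = -1.5 * gain
                w[8 + d, i] = kk
                for off in range(2, N_ORIENT - 1):   # cross-orientation term
                    cc = np.zeros((k, k), dtype=np.float32)
                    cc[k // 2, k // 2] = -0.6 * gain
                    w[8 + d, (i + off) % N_ORIENT] += cc
        elif spec.init == "pool_random":
            # outputs: [0] pooled endpointness ("tipness"), [1:9] smoothed
            # orientation energy, [9:25] endpoint channels, rest random.
            # The designed channels ride along as blur taps so the top-layer
            # patch features expose them directly to the readout.
            w = _rand_kernels(rng, out_c, in_c, k)
            blur = np.ones((k, k), dtype=np.float32) / (k * k)
            w[:_N_CARRY] = 0.0
            for src in range(*_ENDPOINT_SLICE.indices(in_c)):
                w[0, src] = blur * 1.5
            for i in range(N_ORIENT):
                w[1 + i, i] = blur
            for d in range(16):
                w[9 + d, 8 + d] = blur * 1.5
        elif spec.init == "carry_random":
            # first _N_CARRY channels: blur passthrough; rest random
            w = _rand_kernels(rng, out_c, in_c, k)
            blur = np.ones((k, k), dtype=np.float32) / (k * k)
            w[:_N_CARRY] = 0.0
            for i in range(_N_CARRY):
                w[i, i] = blur
        elif spec.init == "random":
            w = _rand_kernels(rng, out_c, in_c, k)
        else:
            raise ValueError(f"unknown filter recipe {spec.init!r} (layer {li})")
        weights.append(w)
        in_c = out_c
    return weights


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def conv_relu(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Valid convolution + relu.  ``x``: (N, C, H, W); ``w``: (O, C, k, k)."""
    k = w.shape[-1]
    if x.shape[-1] < k or x.shape[-2] < k:
        raise ValueError("input smaller than kernel")
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(-2, -1))
    v = v[:, :, ::stride, ::stride]              # (N, C, H', W', k, k)
    out = np.tensordot(v, w.astype(x.dtype), axes=([1, 4, 5], [1, 2, 3]))
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
    np.maximum(out, 0.0, out=out)
    return out


class FeatureTrunk:
    """A fixed-filter convolutional hierarchy.

    Parameters
    ----------
    plan : sequence of LayerSpec
        The layer plan; defaults available as LOCAL_PLAN / GENERIC_PLAN.
    feature_seed : int
        Seed of the random-filter recipe; part of the model configuration.
    """

    def __init__(self, plan: Sequence[LayerSpec] = LOCAL_PLAN,
                 feature_seed: int = 7):
        self.plan = tuple(plan)
        self.feature_seed = int(feature_seed)
        self.weights = _build_weights(self.plan, self.feature_seed)

    @property
    def n_layers(self) -> int:
        return len(self.plan)

    @property
    def out_channels(self) -> int:
        return self.plan[-1].out_channels

    def receptive_field(self, upto: int | None = None) -> int:
        return analytic_receptive_field(self.plan, upto)[0]

    def jump(self, upto: int | None = None) -> int:
        return analytic_receptive_field(self.plan, upto)[1]

    def min_input(self) -> int:
        """Smallest input side for which the top layer produces output."""
        return self.receptive_field()

    def forward(self, x: np.ndarray, collect: Iterable[int] = (),
                ) -> dict[int, np.ndarray]:
        """Run the trunk on a batch of *normalized* images.

        ``x``: (N, H, W) or (N, C, H, W) float.  Returns a dict mapping
        1-based layer index -> activation (N, C, H', W') for the collected
        layers (the final layer is always included).
        """
        if x.ndim == 3:
            x = x[:, None]
        want = set(collect) | {self.n_layers}
        out: dict[int, np.ndarray] = {}
        h = x
        for li, (spec, w) in enumerate(zip(self.plan, self.weights), start=1):
            h = conv_relu(h, w, spec.stride)
            if li in want:
                out[li] = h
        return out

    def features(self, image: np.ndarray, collect: Iterable[int] = (),
                 ) -> dict[int, np.ndarray]:
        """Forward one raw 8-bit image; returns activations without batch axis."""
        maps = self.forward(normalize_image(image)[None], collect)
        return {k: v[0] for k, v in maps.items()}


# ---------------------------------------------------------------------------
# Empirical receptive-field measurement
# ---------------------------------------------------------------------------

def _probe_forward(trunk: FeatureTrunk, batch: np.ndarray) -> np.ndarray:
    out = trunk.forward(batch)[trunk.n_layers]
    return out


def measure_receptive_field(trunk: FeatureTrunk, n_units: int = 10,
                            rel_tol: float = 1e-9, mode: str = "auto",
                            seed: int = 0) -> int:
    """Empirical receptive-field side length of the trunk's top layer.

    Single-pixel perturbations (both signs) are applied to a blank input
    and the minimal square containing every pixel that changes a top-layer
    unit is measured; the maximum extent over at least ``n_units`` randomly
    chosen units is returned.  For plans whose analytic bound exceeds 49 px
    the quadratic pixel probe is replaced by row/column perturbations,
    which measure the same square extent.
    """
    r, j = analytic_receptive_field(trunk.plan)
    margin = 4
    side = r + j + 2 * margin
    base = np.zeros((1, 1, side, side), dtype=np.float64)
    base_out = _probe_forward(trunk, base)       # (1, C, gh, gw)

    if mode == "auto":
        mode = "pixel" if r <= 49 else "line"

    _, c, gh, gw = base_out.shape
    rng = np.random.default_rng(seed)

    def deltas_for(perturbations: np.ndarray) -> np.ndarray:
        """perturbations: (P, side, side) added to blank; returns (P, C, gh, gw) max |delta| over signs."""
        acc = None
        for sign in (1.0, -1.0):
            batch = sign * perturbations[:, None]
            d = np.zeros((perturbations.shape[0], c, gh, gw))
            chunk = 256
            for s in range(0, batch.shape[0], chunk):
                out = _probe_forward(trunk, batch[s:s + chunk].astype(np.float64))
                d[s:s + chunk] = np.abs(out - base_out[0])
            acc = d if acc is None else np.maximum(acc, d)
        return acc

    if mode == "pixel":
        pix = np.eye(side * side, dtype=np.float64).reshape(side * side, side, side)
        dd = deltas_for(pix)                     # (side*side, C, gh, gw)
        dd = dd.reshape(side, side, c, gh, gw)
        tol = rel_tol * dd.max()
        units = [(ch, gy, gx) for ch in range(c)
                 for gy in range(gh) for gx in range(gw)]
        if len(units) > max(n_units, 16):
            idx = rng.choice(len(units), size=max(n_units, 16), replace=False)
            units = [units[i] for i in idx]
        best = 0
        for (ch, gy, gx) in units:
            infl = dd[:, :, ch, gy, gx] > tol
            if not infl.any():
                continue
            ys, xs = np.nonzero(infl)
            ext = max(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
            best = max(best, int(ext))
        return best

    # line mode: whole-row / whole-column perturbations
    rows = np.zeros((side, side, side))
    rows[np.arange(side), np.arange(side), :] = 1.0
    cols = np.transpose(rows, (0, 2, 1))
    ext = []
    for pert in (rows, cols):
        dd = deltas_for(pert)                    # (side, C, gh, gw)
        tol = rel_tol * dd.max()
        units = [(ch, gy, gx) for ch in range(c)
                 for gy in range(gh) for gx in range(gw)]
        if len(units) > max(n_units, 16):
            idx = rng.choice(len(units), size=max(n_units, 16), replace=False)
            units = [units[i] for i in idx]
        best = 0
        for (ch, gy, gx) in units:
            infl = np.nonzero(dd[:, ch, gy, gx] > tol)[0]
            if infl.size:
                best = max(best, int(infl.max() - infl.min() + 1))
        ext.append(best)
    return max(ext)
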