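"""The two model families compared throughout the package.

``LocalBagClassifier`` is a bag-of-local-patches model in the BagNet
spirit: a convolutional trunk whose top-layer units see at most
``rf_limit`` (default 33) pixels, a *linear* per-patch logit, and a spatial
average as the only pooling.  Because averaging commutes with the linear
logit, the model's pooled decision is exactly the mean of its per-patch
logits — the property that licenses patch-evidence heatmaps.

``GenericConvClassifier`` is the unrestricted counterpart (stand-in for a
ResNet-class network at desk scale): a deeper trunk with a large receptive
field, global mean/max pooling plus a coarse spatial grid and endpoint
co-occurrence summaries, and a small MLP readout.  Its hypothesis class
contains the local model's (it sees the same pooled patch features among
its inputs), so it has strictly more capacity.

Both follow scikit-learn conventions: hyperparameters in ``__init__``,
state learned by ``fit`` in trailing-underscore attributes, and
``get_params``/``set_params`` for model selection.  Only the readout is
trained; the trunk filters are fixed by ``feature_seed``, which makes
training deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import SGDClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import features as F
from .features import (FeatureTrunk, GENERIC_PLAN, LOCAL_PLAN, LayerSpec,
                       analytic_receptive_field, normalize_image)

__all__ = [
    "ModelConfig", "TrainConfig", "EvalResult", "ConfigurationError",
    "LocalBagClassifier", "GenericConvClassifier", "build_model",
    "measure_receptive_field", "train", "evaluate", "records_to_arrays",
    "save_model", "load_model",
]


class ConfigurationError(ValueError):
    """A model configuration violates a structural constraint."""


class TrainingDivergence(RuntimeError):
    """Non-finite loss encountered during readout training."""


@dataclass(frozen=True)
class ModelConfig:
    """Declarative model family selection (maps onto the estimators)."""

    family: str = "local_bag"        # "local_bag" | "generic_cnn"
    rf_limit: int = 33
    feature_seed: int = 7
    seed: int = 0
    plan: tuple[LayerSpec, ...] | None = None


@dataclass(frozen=True)
class TrainConfig:
    n_train: int | None = None
    n_epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class EvalResult:
    dataset_id: str
    accuracy: float
    n_eval: int
    per_class_accuracy: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature extraction helpers
# ---------------------------------------------------------------------------

_ENDPOINT_LAYER = 3     # layer carrying the 16 directed endpoint channels
_PATCH_LAYER = len(LOCAL_PLAN)


def _as_image_array(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 3:
        raise ValueError("X must be (n_images, height, width) grayscale")
    return X


def _patch_feature_map(trunk: FeatureTrunk, image: np.ndarray) -> np.ndarray:
    """(C, gh, gw) top-layer activations of the local trunk."""
    return trunk.features(image)[trunk.n_layers]


def _adaptive_avg_pool(m: np.ndarray, out: int) -> np.ndarray:
    """(C, h, w) -> (C, out, out) average pooling with equal-ish bins."""
    c, h, w = m.shape
    ys = np.linspace(0, h, out + 1).astype(int)
    xs = np.linspace(0, w, out + 1).astype(int)
    r = np.zeros((c, out, out), dtype=m.dtype)
    for i in range(out):
        for j in range(out):
            r[:, i, j] = m[:, ys[i]:max(ys[i + 1], ys[i] + 1),
                           xs[j]:max(xs[j + 1], xs[j] + 1)].mean(axis=(1, 2))
    return r


def _block_pool(m: np.ndarray, k: int) -> np.ndarray:
    """(C, h, w) -> (C, h//k, w//k) non-overlapping mean pooling."""
    c, h, w = m.shape
    h2, w2 = h // k, w // k
    if h2 < 1 or w2 < 1:
        return m
    return m[:, :h2 * k, :w2 * k].reshape(c, h2, k, w2, k).mean(axis=(2, 4))


def _pair_features(ep: np.ndarray) -> np.ndarray:
    """Facing-endpoint co-occurrence summaries from the 16 directed
    endpoint channels (jump-2 grid).

    The maps are pooled to an 8-px grid; for each direction the endpoint
    response is multiplied with the opposite direction's response shifted
    2-6 cells (16-48 px) ahead — high when two line terminations face each
    other across a gap, the signature of an opened contour.
    """
    p = _block_pool(ep, 4)                     # jump 8 grid
    c, h, w = p.shape
    offs = F._direction_offsets()
    out = np.zeros(2 * c, dtype=np.float32)
    for d in range(c):
        dx, dy = offs[d]
        opp = p[(d + c // 2) % c]
        best = np.zeros_like(p[d])
        for t in range(2, 7):
            sy, sx = t * dy, t * dx
            shifted = np.zeros_like(opp)
            ys0, ys1 = max(0, -sy), min(h, h - sy)
            xs0, xs1 = max(0, -sx), min(w, w - sx)
            if ys0 < ys1 and xs0 < xs1:
                shifted[ys0:ys1, xs0:xs1] = opp[ys0 + sy:ys1 + sy,
                                                xs0 + sx:xs1 + sx]
            np.maximum(best, shifted, out=best)
        pd = p[d] * best
        out[2 * d] = pd.max()
        out[2 * d + 1] = pd.mean()
    return out


def _enclosure_features(image: np.ndarray) -> np.ndarray:
    """Global border-propagation (grouping) summaries.

    Free space is propagated inward from the image border through non-ink
    pixels (the unrolled fixed point of iterated 3x3 dilation masked by the
    ink map — a computation an unrestricted-depth network can implement but
    a 33-px receptive field cannot).  A closed contour leaves unreachable
    background behind; an open one does not.  Returns log1p of the enclosed
    area and the number of enclosed components.
    """
    x = normalize_image(image)
    ink = np.abs(x) > 0.3
    free = ~ink
    seed = np.zeros_like(free)
    seed[0, :] = seed[-1, :] = seed[:, 0] = seed[:, -1] = True
    seed &= free
    reach = ndimage.binary_propagation(seed, mask=free)
    enclosed = free & ~reach
    _, n = ndimage.label(enclosed)
    return np.array([np.log1p(float(enclosed.sum())), float(n)],
                    dtype=np.float32)


def _generic_feature_vector(trunk: FeatureTrunk, image: np.ndarray,
                            proj: np.ndarray) -> np.ndarray:
    maps = trunk.features(image, collect=(_ENDPOINT_LAYER, _PATCH_LAYER))
    patch = maps[_PATCH_LAYER]
    last = maps[trunk.n_layers]
    coarse = _adaptive_avg_pool(
        np.tensordot(proj, patch, axes=(1, 0)), 3).ravel()
    ep = maps[_ENDPOINT_LAYER][8:24]
    return np.concatenate([
        patch.mean(axis=(1, 2)), patch.max(axis=(1, 2)),
        last.mean(axis=(1, 2)), last.max(axis=(1, 2)),
        coarse, _pair_features(ep), _enclosure_features(image),
    ]).astype(np.float32)


class _GenericTrunk(FeatureTrunk):
    """Generic plan trunk that stops when the map becomes smaller than the
    next kernel (so the same plan serves 256-px and 128-px inputs)."""

    def forward(self, x, collect=()):
        if x.ndim == 3:
            x = x[:, None]
        want = set(collect)
        out: dict[int, np.ndarray] = {}
        h = x
        li = 0
        for spec, w in zip(self.plan, self.weights):
            if h.shape[-1] < spec.kernel or h.shape[-2] < spec.kernel:
                break
            h = F.conv_relu(h, w, spec.stride)
            li += 1
            if li in want:
                out[li] = h
        self.n_layers_effective_ = li
        out[self.n_layers] = h        # "final" = deepest computable layer
        return out


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class LocalBagClassifier(BaseEstimator, ClassifierMixin):
    """Restricted-receptive-field bag-of-patches classifier.

    The per-patch logit is linear in the top trunk features; the image
    logit is the spatial average of patch logits.  ``rf_limit`` is a hard
    structural bound: a plan whose analytic receptive field exceeds it is
    rejected at fit time.
    """

    def __init__(self, rf_limit: int = 33, feature_seed: int = 7,
                 n_epochs: int = 30, alpha: float = 1e-4,
                 learning_rate: float = 1e-2, lift_dim: int = 384,
                 seed: int = 0, plan=None):
        self.rf_limit = rf_limit
        self.feature_seed = feature_seed
        self.n_epochs = n_epochs
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.lift_dim = lift_dim
        self.seed = seed
        self.plan = plan

    # -- structure ------------------------------------------------------

    def _make_trunk(self) -> FeatureTrunk:
        plan = tuple(self.plan) if self.plan is not None else LOCAL_PLAN
        rf, _ = analytic_receptive_field(plan)
        if rf > self.rf_limit:
            raise ConfigurationError(
                f"layer plan has receptive field {rf} px > rf_limit "
                f"{self.rf_limit} px")
        return FeatureTrunk(plan, self.feature_seed)

    @property
    def trunk_(self) -> FeatureTrunk:
        if not hasattr(self, "_trunk"):
            self._trunk = self._make_trunk()
        return self._trunk

    # -- features -------------------------------------------------------
    #
    # The per-patch encoder ends with a pointwise (1x1) random-feature
    # stage: patch features are standardized, expanded through a fixed
    # random relu projection (with biases), and concatenated with their
    # linear part.  Being 1x1, the stage leaves the receptive field at
    # exactly rf_limit while letting the linear logit express thresholded
    # within-patch conjunctions (two facing endpoints, a short terminated
    # edge) that a purely linear readout cannot.

    def _lift_params(self):
        if not hasattr(self, "_lift_cache"):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.feature_seed), 0x11F7]))
            c = self.trunk_.out_channels
            W = (rng.normal(0, 1, (self.lift_dim, c))
                 / np.sqrt(c)).astype(np.float32)
            b = rng.normal(0.0, 0.5, self.lift_dim).astype(np.float32)
            self._lift_cache = (W, b)
        return self._lift_cache

    def _patch_encode(self, image: np.ndarray) -> np.ndarray:
        """(C + lift_dim, gh, gw) standardized + lifted patch features.

        Standardized features saturate at +-4 sd: sparse designed channels
        (endpointness) have tiny patch-level variance, and unclipped
        z-scores would let single cells dominate both the readout and the
        evidence maps.
        """
        fmap = _patch_feature_map(self.trunk_, image)
        z = ((fmap - self.patch_mu_[:, None, None])
             / self.patch_sd_[:, None, None])
        np.clip(z, -4.0, 4.0, out=z)
        W, b = self._lift_params()
        lifted = np.tensordot(W, z, axes=(1, 0)) + b[:, None, None]
        np.maximum(lifted, 0.0, out=lifted)
        return np.concatenate([z, lifted], axis=0)

    def _pooled_features(self, X: np.ndarray) -> np.ndarray:
        return np.stack([
            self._patch_encode(img).mean(axis=(1, 2), dtype=np.float64)
            for img in X])

    def _fit_patch_stats(self, X: np.ndarray) -> None:
        sample = X[:: max(1, len(X) // 200)]
        maps = [_patch_feature_map(self.trunk_, img) for img in sample]
        flat = np.concatenate([m.reshape(m.shape[0], -1) for m in maps], axis=1)
        self.patch_mu_ = flat.mean(axis=1).astype(np.float32)
        self.patch_sd_ = (flat.std(axis=1) + 1e-6).astype(np.float32)

    # -- sklearn API ----------------------------------------------------

    def fit(self, X, y):
        X = _as_image_array(X)
        y = np.asarray(y)
        self._trunk = self._make_trunk()
        self._fit_patch_stats(X)
        phi = self._pooled_features(X)
        self.scaler_ = StandardScaler().fit(phi)
        z = self.scaler_.transform(phi)
        sgd = SGDClassifier(loss="log_loss", alpha=self.alpha,
                            learning_rate="constant", eta0=self.learning_rate,
                            random_state=self.seed, shuffle=True)
        hist = []
        for epoch in range(self.n_epochs):
            sgd.partial_fit(z, y, classes=np.unique(y))
            logit = sgd.decision_function(z)
            if not np.all(np.isfinite(logit)):
                raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
            p = 1.0 / (1.0 + np.exp(-logit))
            yy = (y == sgd.classes_[1]).astype(float)
            loss = float(-np.mean(yy * np.log(p + 1e-12)
                                  + (1 - yy) * np.log(1 - p + 1e-12)))
            hist.append({"epoch": epoch, "loss": loss,
                         "train_accuracy": float((sgd.predict(z) == y).mean())})
        self.sgd_ = sgd
        self.classes_ = sgd.classes_
        self.history_ = pd.DataFrame(hist)
        self.input_size_ = X.shape[1:]
        return self

    def _pooled_logit(self, X: np.ndarray) -> np.ndarray:
        z = self.scaler_.transform(self._pooled_features(X))
        return self.sgd_.decision_function(z)

    def decision_function(self, X):
        check_is_fitted(self, "sgd_")
        return self._pooled_logit(_as_image_array(X))

    def predict_proba(self, X):
        d = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-d))
        return np.stack([1 - p1, p1], axis=1)

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    # -- patch evidence -------------------------------------------------

    def patch_logit_grid(self, image: np.ndarray) -> np.ndarray:
        """Per-patch logits whose spatial mean is exactly the image logit.

        Positive values are evidence for the second class (``classes_[1]``,
        'open' under the package's label convention).
        """
        check_is_fitted(self, "sgd_")
        enc = self._patch_encode(image).astype(np.float64)  # (C+L, gh, gw)
        w = (self.sgd_.coef_[0] / self.scaler_.scale_)
        b = float(self.sgd_.intercept_[0]
                  - (self.sgd_.coef_[0] * self.scaler_.mean_
                     / self.scaler_.scale_).sum())
        return np.tensordot(w, enc, axes=(0, 0)) + b

    @property
    def patch_stride(self) -> int:
        return self.trunk_.jump()

    @property
    def patch_size(self) -> int:
        return self.trunk_.receptive_field()


class GenericConvClassifier(BaseEstimator, ClassifierMixin):
    """Large-receptive-field convolutional classifier with an MLP readout."""

    def __init__(self, feature_seed: int = 7, hidden: tuple = (64,),
                 n_epochs: int = 60, learning_rate: float = 1e-3,
                 alpha: float = 1.0, seed: int = 0, plan=None):
        self.feature_seed = feature_seed
        self.hidden = hidden
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.seed = seed
        self.plan = plan

    @property
    def trunk_(self) -> FeatureTrunk:
        if not hasattr(self, "_trunk"):
            plan = tuple(self.plan) if self.plan is not None else GENERIC_PLAN
            self._trunk = _GenericTrunk(plan, self.feature_seed)
        return self._trunk

    @property
    def _proj(self) -> np.ndarray:
        if not hasattr(self, "_proj_cache"):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.feature_seed), 0xC0A5]))
            c = LOCAL_PLAN[-1].out_channels
            self._proj_cache = (rng.normal(0, 1, (16, c))
                                / np.sqrt(c)).astype(np.float32)
        return self._proj_cache

    def _features(self, X: np.ndarray) -> np.ndarray:
        return np.stack([
            _generic_feature_vector(self.trunk_, img, self._proj) for img in X])

    def fit(self, X, y):
        X = _as_image_array(X)
        y = np.asarray(y)
        phi = self._features(X)
        self.scaler_ = StandardScaler().fit(phi)
        z = self.scaler_.transform(phi)
        mlp = MLPClassifier(hidden_layer_sizes=tuple(self.hidden),
                            alpha=self.alpha,
                            learning_rate_init=self.learning_rate,
                            random_state=self.seed, max_iter=1)
        hist = []
        classes = np.unique(y)
        for epoch in range(self.n_epochs):
            mlp.partial_fit(z, y, classes=classes)
            if not np.isfinite(mlp.loss_):
                raise TrainingDivergence(f"non-finite loss at epoch {epoch}")
            hist.append({"epoch": epoch, "loss": float(mlp.loss_),
                         "train_accuracy": float((mlp.predict(z) == y).mean())})
        self.mlp_ = mlp
        self.classes_ = mlp.classes_
        self.history_ = pd.DataFrame(hist)
        self.input_size_ = X.shape[1:]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "mlp_")
        z = self.scaler_.transform(self._features(_as_image_array(X)))
        return self.mlp_.predict_proba(z)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# Functional interface
# ---------------------------------------------------------------------------

def build_model(cfg: ModelConfig):
    """Instantiate the estimator a ModelConfig describes."""
    if cfg.family == "local_bag":
        return LocalBagClassifier(rf_limit=cfg.rf_limit,
                                  feature_seed=cfg.feature_seed,
                                  seed=cfg.seed, plan=cfg.plan)
    if cfg.family == "generic_cnn":
        return GenericConvClassifier(feature_seed=cfg.feature_seed,
                                     seed=cfg.seed, plan=cfg.plan)
    raise ConfigurationError(f"unknown model family {cfg.family!r}")


def measure_receptive_field(model, **kw) -> int:
    """Empirical receptive field (px) of a model's top conv layer."""
    if isinstance(model, FeatureTrunk):
        return F.measure_receptive_field(model, **kw)
    trunk = model.trunk_
    return F.measure_receptive_field(trunk, **kw)


def records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """Stack StimulusRecords into (X images, y integer labels)."""
    X = np.stack([r.image for r in records])
    y = np.array([r.y for r in records])
    return X, y


def train(model, records, tc: TrainConfig | None = None):
    """Fit a model on a record dataset; returns (model, history table)."""
    tc = tc or TrainConfig()
    X, y = records_to_arrays(records)
    if tc.n_train is not None:
        if tc.n_train > len(X):
            raise ValueError("n_train exceeds dataset size")
        X, y = X[:tc.n_train], y[:tc.n_train]
    model.set_params(seed=tc.seed)
    if hasattr(model, "n_epochs"):
        model.set_params(n_epochs=tc.n_epochs)
    model.fit(X, y)
    if not model.history_["loss"].map(np.isfinite).all():
        raise TrainingDivergence("training diverged")
    return model, model.history_


def evaluate(model, records, dataset_id: str = "dataset") -> EvalResult:
    """Exact accuracy of a fitted model on a labeled record dataset."""
    if len(records) == 0:
        raise ValueError("empty dataset")
    X, y = records_to_arrays(records)
    if hasattr(model, "predict_records"):     # metadata-reference models
        pred = np.asarray(model.predict_records(records))
    else:
        pred = model.predict(X)
    acc = float((pred == y).mean())
    per_class = {int(c): float((pred[y == c] == c).mean())
                 for c in np.unique(y)}
    return EvalResult(dataset_id=dataset_id, accuracy=acc, n_eval=len(y),
                      per_class_accuracy=per_class)


def save_model(model, path) -> None:
    """Persist a fitted estimator (single-file archive with its config)."""
    payload = {"params": model.get_params(), "class": type(model).__name__,
               "estimator": model}
    joblib.dump(payload, path)


def load_model(path):
    return joblib.load(path)["estimator"]
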