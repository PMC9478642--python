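"""Learned denoising, semantic segmentation and bundle picking.

Two small neural networks operate on micrographs downsampled to the working
binning:

* a **denoiser** — a multilayer perceptron regressor mapping a square window
  of the noisy image to the clean value at the window center (a patch-based
  denoising auto-association network), and
* a **segmenter** — an MLP classifier mapping a multiscale stack of windows
  (the same window at 1x, 2x, 4x decimation, giving a wide receptive field)
  to the class of the center pixel: background / single filament /
  two-filament bundle / higher-order assembly.

Both nets are deliberately tiny (tens of thousands of weights) so CPU
training on a few hundred synthetic patches takes minutes. Picking converts
the bundle-class probability map into particle coordinates by thresholding,
skeletonizing each connected component, walking the longest centerline path
and emitting picks at a fixed arc-length step.

All training and inference is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.neural_network import MLPClassifier, MLPRegressor
from skimage.morphology import skeletonize, remove_small_objects

from .errors import ConfigError, FormatError
from .formats import Micrograph
from .synthgen import CLASS_BUNDLE2, CLASS_HIGHER, CLASS_SINGLE, N_CLASSES

__all__ = [
    "NetSpec", "SegMask", "Pick", "PickParams",
    "train_denoiser", "train_segmenter", "infer",
    "picks_from_mask", "BundlePicker", "evaluate_picks",
]


# ---------------------------------------------------------------------------
# Specs and containers
# ---------------------------------------------------------------------------

@dataclass
class NetSpec:
    """Architecture configuration for the denoiser / segmenter.

    ``window`` is the square window side (pixels at working binning, odd);
    ``scales`` are the decimation factors of the multiscale feature stack
    (depth = number of scales); ``hidden`` the MLP hidden-layer widths;
    ``binning`` the extra downsampling applied to inputs before windowing.
    """

    arch: str = "segmenter"            # 'denoiser' | 'segmenter'
    window: int = 11
    scales: tuple[int, ...] = (1, 2, 4)
    hidden: tuple[int, ...] = (96,)
    n_classes: int = N_CLASSES
    binning: int = 2

    def __post_init__(self) -> None:
        if self.arch not in ("denoiser", "segmenter"):
            raise ConfigError(f"unknown architecture {self.arch!r}")
        if self.window % 2 != 1:
            raise ConfigError(f"window must be odd, got {self.window}")
        for s in self.scales:
            if s < 1 or (s & (s - 1)):
                raise ConfigError(f"scales must be powers of 2, got {self.scales}")
        if self.arch == "segmenter" and self.n_classes != N_CLASSES:
            raise ConfigError(f"default segmenter uses {N_CLASSES} classes")

    @property
    def depth(self) -> int:
        return len(self.scales)

    @property
    def n_features(self) -> int:
        return self.window ** 2 * len(self.scales)


DENOISER_SPEC = NetSpec(arch="denoiser", window=17, scales=(1,), hidden=(64,))
SEGMENTER_SPEC = NetSpec(arch="segmenter", window=11, scales=(1, 2, 4, 8), hidden=(96,))


@dataclass
class SegMask:
    """Per-pixel class probabilities and argmax labels for one micrograph."""

    probs: np.ndarray          # (n_classes, ny, nx), sums to 1 per pixel
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.probs.sum(axis=0)
        if np.abs(s - 1.0).max() > 1e-5:
            raise FormatError("class probabilities must sum to 1 per pixel")

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.probs, axis=0).astype(np.uint8)


@dataclass
class Pick:
    """One bundle particle pick (pixel coordinates in the source image)."""

    x: float
    y: float
    score: float
    component: int
    angle: float               # local bundle axis angle, degrees
    cls: int = CLASS_BUNDLE2


@dataclass
class PickParams:
    """Pick-extraction parameters, in pixels of the mask they are applied to.
    :class:`BundlePicker` rescales them from full-resolution micrograph pixels
    to the working binning automatically."""

    threshold: float = 0.5        # bundle2 probability threshold
    step: float = 50.0            # pick spacing along the centerline, px
    min_len: float = 60.0         # minimum centerline length, px
    higher_frac: float = 0.25     # reject picks overlapping higher-class pixels
    box: int = 48                 # pick box (px) for the overlap rule
    min_area: int = 64            # drop tiny binary components before skeletonizing
    smooth_sigma: float = 3.0     # Gaussian smoothing of probability maps, px
    max_single_prob: float = 0.07  # component veto: mean single-class probability
    max_higher_prob: float = 0.05  # component veto: mean higher-class probability

    def rescaled(self, factor: float) -> "PickParams":
        return PickParams(self.threshold, self.step / factor, self.min_len / factor,
                          self.higher_frac, max(int(round(self.box / factor)), 3),
                          max(int(round(self.min_area / factor ** 2)), 4),
                          self.smooth_sigma / factor,
                          self.max_single_prob, self.max_higher_prob)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _bin2d(img: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return np.asarray(img, np.float32)
    ny, nx = img.shape
    ny2, nx2 = ny // b * b, nx // b * b
    return img[:ny2, :nx2].reshape(ny2 // b, b, nx2 // b, b).mean(axis=(1, 3)).astype(np.float32)


def _standardize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, np.float64)
    sd = img.std()
    return ((img - img.mean()) / (sd if sd > 0 else 1.0)).astype(np.float32)


def _padded_views(img: np.ndarray, spec: NetSpec) -> list[np.ndarray]:
    """Per-scale sliding-window views, padded so every pixel has a window."""
    from numpy.lib.stride_tricks import sliding_window_view

    w = spec.window
    half = w // 2
    views = []
    for s in spec.scales:
        dec = _bin2d(img, s) if s > 1 else img
        pad = np.pad(dec, half, mode="reflect")
        views.append(sliding_window_view(pad, (w, w)))
    return views


def _features_at(views: list[np.ndarray], spec: NetSpec,
                 ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    parts = []
    for s, view in zip(spec.scales, views):
        yi = np.clip(ys // s, 0, view.shape[0] - 1)
        xi = np.clip(xs // s, 0, view.shape[1] - 1)
        parts.append(view[yi, xi].reshape(len(ys), -1))
    return np.concatenate(parts, axis=1)


def _bin_labels(labels: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return labels
    ny, nx = labels.shape
    ny2, nx2 = ny // b * b, nx // b * b
    return labels[:ny2, :nx2].reshape(ny2 // b, b, nx2 // b, b).max(axis=(1, 3))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedNet:
    """An MLP with its NetSpec and training history."""

    spec: NetSpec
    mlp: object
    history: dict
    pixel_size: float


def _as_triples(dataset) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Accept in-memory (noisy, clean, labels) triples or a dataset directory
    written by :func:`filbundle.synthgen.emit_dataset`."""
    if isinstance(dataset, (str, bytes)) or hasattr(dataset, "__fspath__"):
        from pathlib import Path
        from . import formats

        d = Path(dataset)
        triples = []
        for noisy_path in sorted(d.glob("*_noisy.mrc")):
            stem = noisy_path.name.removesuffix("_noisy.mrc")
            noisy = formats.read_micrograph(noisy_path)
            clean = formats.read_micrograph(d / f"{stem}_clean.mrc")
            labels = formats.read_map(d / f"{stem}_labels.mrc").data[0].astype(np.uint8)
            triples.append((noisy.data, clean.data, labels))
        if not triples:
            raise FormatError(f"no *_noisy.mrc scenes found in {d}")
        return triples
    return list(dataset)


def train_denoiser(dataset, spec: NetSpec | None = None, epochs: int = 20,
                   seed: int = 0, samples_per_patch: int = 400,
                   pixel_size: float = 4.4) -> TrainedNet:
    """Train the windowed MLP denoiser on (noisy, clean) pairs.

    Minimizes mean-squared error from noisy windows to the clean center
    value (both images standardized per frame). ``history['loss']`` records
    the training MSE per epoch. Deterministic given the seed.
    """
    if spec is None:
        spec = DENOISER_SPEC
    triples = _as_triples(dataset)
    if not triples:
        raise ConfigError("empty dataset")
    rng = np.random.default_rng(seed)
    X_parts, y_parts = [], []
    for noisy, clean, _ in triples:
        nb = _standardize(_bin2d(noisy, spec.binning))
        cb = _standardize(_bin2d(clean, spec.binning))
        if min(nb.shape) < spec.window:
            raise ConfigError(f"patch {nb.shape} smaller than window {spec.window}")
        views = _padded_views(nb, spec)
        ys = rng.integers(0, nb.shape[0], samples_per_patch)
        xs = rng.integers(0, nb.shape[1], samples_per_patch)
        X_parts.append(_features_at(views, spec, ys, xs))
        y_parts.append(cb[ys, xs])
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    mlp = MLPRegressor(hidden_layer_sizes=spec.hidden, batch_size=256,
                       learning_rate_init=1e-3, random_state=seed, max_iter=1,
                       warm_start=False, shuffle=False)
    history = {"loss": []}
    order_rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        idx = order_rng.permutation(len(X))
        mlp.partial_fit(X[idx], y[idx])
        history["loss"].append(float(np.mean((mlp.predict(X) - y) ** 2)))
    return TrainedNet(spec, mlp, history, pixel_size)


#: default class weights: background is oversampled to suppress false
#: positives on empty ice; filament classes weighted equally
DEFAULT_CLASS_WEIGHTS = {0: 3.0, 1: 1.0, 2: 1.0, 3: 1.0}


def train_segmenter(dataset, spec: NetSpec | None = None, epochs: int = 25,
                    seed: int = 0, samples_per_class: int = 150,
                    class_weights: dict[int, float] | None = None,
                    holdout_frac: float = 0.1, denoiser: TrainedNet | None = None,
                    pixel_size: float = 4.4) -> TrainedNet:
    """Train the multiscale-window MLP segmenter on (noisy, labels) pairs.

    Cross-entropy is weighted per class by resampling pixels proportionally
    to ``class_weights`` (uniform per available class by default). When a
    ``denoiser`` is passed, its output is the segmenter's input (the default
    pipeline coupling); otherwise the raw standardized image is used.
    ``history`` records per-epoch training loss and per-class pixel accuracy
    on a held-out patch split.
    """
    if spec is None:
        spec = SEGMENTER_SPEC
    triples = _as_triples(dataset)
    if not triples:
        raise ConfigError("empty dataset")
    if class_weights is None:
        class_weights = dict(DEFAULT_CLASS_WEIGHTS)
    rng = np.random.default_rng(seed)

    n_hold = max(1, int(round(holdout_frac * len(triples)))) if len(triples) > 1 else 0
    hold, train = triples[:n_hold], triples[n_hold:]

    def pixel_samples(subset):
        X_parts, y_parts = [], []
        for noisy, _, labels in subset:
            img = _segmenter_input(noisy, spec, denoiser)
            lab = _bin_labels(labels, spec.binning)[: img.shape[0], : img.shape[1]]
            views = _padded_views(img, spec)
            for c in range(spec.n_classes):
                ys, xs = np.nonzero(lab == c)
                if len(ys) == 0:
                    continue
                k = max(1, int(round(samples_per_class * class_weights.get(c, 1.0))))
                sel = rng.integers(0, len(ys), min(k, len(ys)))
                X_parts.append(_features_at(views, spec, ys[sel], xs[sel]))
                y_parts.append(lab[ys[sel], xs[sel]])
        return np.vstack(X_parts), np.concatenate(y_parts)

    X, y = pixel_samples(train)
    classes = np.arange(spec.n_classes)
    mlp = MLPClassifier(hidden_layer_sizes=spec.hidden, batch_size=256,
                        learning_rate_init=1e-3, random_state=seed, max_iter=1,
                        shuffle=False)
    history = {"loss": [], "holdout_accuracy": []}
    order_rng = np.random.default_rng(seed + 1)
    Xh, yh = pixel_samples(hold) if hold else (None, None)
    for _ in range(epochs):
        idx = order_rng.permutation(len(X))
        mlp.partial_fit(X[idx], y[idx], classes=classes)
        history["loss"].append(float(mlp.loss_))
        if Xh is not None:
            pred = mlp.predict(Xh)
            acc = {int(c): float(np.mean(pred[yh == c] == c))
                   for c in np.unique(yh)}
            history["holdout_accuracy"].append(acc)
    return TrainedNet(spec, mlp, history, pixel_size)


def _segmenter_input(noisy: np.ndarray, spec: NetSpec,
                     denoiser: TrainedNet | None) -> np.ndarray:
    img = _standardize(_bin2d(noisy, spec.binning))
    if denoiser is not None:
        # denoiser runs at its own binning; here both default to the same
        img = _denoise_array(img, denoiser, binned=True)
    return img


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def _predict_grid(img: np.ndarray, net: TrainedNet, stride: int = 1,
                  tile_rows: int = 128, proba: bool = False) -> np.ndarray:
    """Windowed prediction over a strided pixel grid, tiled over rows to
    bound memory. Per-pixel predictions are independent, so any tiling or
    overlap produces identical output."""
    spec = net.spec
    views = _padded_views(img, spec)
    gy = np.arange(0, img.shape[0], stride)
    gx = np.arange(0, img.shape[1], stride)
    out = None
    for r0 in range(0, len(gy), tile_rows):
        rows = gy[r0: r0 + tile_rows]
        ys = np.repeat(rows, len(gx))
        xs = np.tile(gx, len(rows))
        X = _features_at(views, spec, ys, xs)
        if proba:
            pred = net.mlp.predict_proba(X).astype(np.float32)
            pred = pred.reshape(len(rows), len(gx), -1)
        else:
            pred = net.mlp.predict(X).astype(np.float32).reshape(len(rows), len(gx))
        if out is None:
            shape = (len(gy), len(gx)) + (() if not proba else (pred.shape[-1],))
            out = np.empty(shape, dtype=np.float32)
        out[r0: r0 + len(rows)] = pred
    return out


def _upsample(grid: np.ndarray, stride: int, shape: tuple[int, int]) -> np.ndarray:
    if stride == 1:
        return grid[: shape[0], : shape[1]]
    z = ndimage.zoom(grid, stride, order=1, grid_mode=True, mode="nearest")
    return z[: shape[0], : shape[1]]


def _denoise_array(binned_std: np.ndarray, net: TrainedNet, binned: bool,
                   stride: int = 1) -> np.ndarray:
    pred = _predict_grid(binned_std, net, stride=stride)
    return _upsample(pred, stride, binned_std.shape)


def infer(net: TrainedNet, micrograph: Micrograph, tile_rows: int = 128,
          stride: int = 1, denoiser: TrainedNet | None = None,
          allow_rescale: bool = True):
    """Run a trained net on a full micrograph.

    Returns a denoised :class:`Micrograph` for a denoiser net, or a
    :class:`SegMask` (at full input resolution) for a segmenter. Micrographs
    whose pixel size differs from the training pixel size are rescaled when
    ``allow_rescale`` (always warned via provenance); a mismatch beyond 20%
    with rescaling disabled is an error.
    """
    spec = net.spec
    scale = micrograph.pixel_size / net.pixel_size
    data = micrograph.data
    rescaled = False
    if abs(scale - 1.0) > 1e-3:
        if not allow_rescale and abs(scale - 1.0) > 0.2:
            raise ConfigError(
                f"pixel size {micrograph.pixel_size} differs from training "
                f"{net.pixel_size} by more than 20% and rescaling is disabled"
            )
        data = ndimage.zoom(data, scale, order=1)
        rescaled = True
    img = _standardize(_bin2d(data, spec.binning))

    if spec.arch == "denoiser":
        den = _predict_grid(img, net, stride=stride, tile_rows=tile_rows)
        den = _upsample(den, stride, img.shape)
        up = ndimage.zoom(den, spec.binning, order=1, grid_mode=True, mode="nearest")
        up = up[: data.shape[0], : data.shape[1]]
        if rescaled:  # map back onto the original sampling
            out_shape = micrograph.data.shape
            up = ndimage.zoom(up, (out_shape[0] / up.shape[0],
                                   out_shape[1] / up.shape[1]),
                              order=1, grid_mode=True, mode="nearest")
        full = np.zeros_like(micrograph.data, dtype=np.float32)
        full[: up.shape[0], : up.shape[1]] = up[: full.shape[0], : full.shape[1]]
        return Micrograph(full, micrograph.pixel_size, micrograph.id)

    if denoiser is not None:
        img = _denoise_array(img, denoiser, binned=True)
    probs = _predict_grid(img, net, stride=stride, tile_rows=tile_rows, proba=True)
    probs = np.stack([_upsample(probs[..., c], stride, img.shape)
                      for c in range(probs.shape[-1])])
    probs = np.clip(probs, 0, None)
    probs /= probs.sum(axis=0, keepdims=True)
    return SegMask(
        probs,
        provenance={"input": micrograph.id, "binning": spec.binning,
                    "stride": stride, "rescaled": rescaled,
                    "mask_pixel_size": net.pixel_size * spec.binning},
    )


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------

def _skeleton_longest_path(skel: np.ndarray) -> list[tuple[int, int]]:
    """Longest path through a skeleton (double BFS sweep); prunes branches."""
    pts = list(zip(*np.nonzero(skel)))
    if not pts:
        return []
    ptset = set(pts)

    def neighbors(p):
        y, x = p
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                q = (y + dy, x + dx)
                if q in ptset:
                    yield q

    def bfs(start):
        from collections import deque

        prev = {start: None}
        dist = {start: 0.0}
        far, far_d = start, 0.0
        dq = deque([start])
        while dq:
            p = dq.popleft()
            for q in neighbors(p):
                if q not in prev:
                    prev[q] = p
                    d = dist[p] + np.hypot(q[0] - p[0], q[1] - p[1])
                    dist[q] = d
                    if d > far_d:
                        far, far_d = q, d
                    dq.append(q)
        return far, prev

    a, _ = bfs(pts[0])
    b, prev = bfs(a)
    path = []
    p = b
    while p is not None:
        path.append(p)
        p = prev[p]
    return path[::-1]


def _smooth_path(pth: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of a pixel path; removes the staircase wiggle
    of 8-connected skeletons so arc length reflects the true centerline."""
    if len(pth) < window:
        return pth
    kernel = np.ones(window) / window
    sm = np.column_stack([
        np.convolve(np.pad(pth[:, i], window // 2, mode="edge"), kernel, "valid")
        for i in range(2)
    ])
    sm[0], sm[-1] = pth[0], pth[-1]
    return sm


def _extend_path_ends(pth: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Extend the centerline beyond the skeleton endpoints by the local
    component half-width (skeletonization erodes ribbon ends by about that
    much)."""
    if len(pth) < 5:
        return pth
    out = [pth]
    for end, inner in ((0, 4), (-1, -5)):
        p = pth[end]
        tangent = p - pth[inner]
        n = np.linalg.norm(tangent)
        if n == 0:
            continue
        yi = int(np.clip(round(p[0]), 0, dist.shape[0] - 1))
        xi = int(np.clip(round(p[1]), 0, dist.shape[1] - 1))
        ext = p + tangent / n * float(dist[yi, xi])
        if end == 0:
            out.insert(0, ext[None])
        else:
            out.append(ext[None])
    return np.vstack(out)


def picks_from_mask(mask: SegMask, params: PickParams | None = None,
                    scale: float = 1.0) -> list[Pick]:
    """Convert a segmentation mask into bundle picks.

    Thresholds the bundle-class probability, skeletonizes each connected
    component, walks the longest centerline path and emits a pick every
    ``params.step`` pixels of arc length. Components shorter than
    ``params.min_len`` are rejected, as are picks whose box contains more
    than ``params.higher_frac`` higher-class pixels. Pick coordinates are
    multiplied by ``scale`` (e.g. the working binning) on output.
    """
    if params is None:
        params = PickParams()
    probs = mask.probs
    if params.smooth_sigma > 0:
        probs = np.stack([ndimage.gaussian_filter(p, params.smooth_sigma)
                          for p in probs])
        probs = probs / probs.sum(axis=0, keepdims=True)
    prob = probs[CLASS_BUNDLE2]
    labels_img = np.argmax(probs, axis=0)
    binary = prob >= params.threshold
    binary = remove_small_objects(binary, max_size=params.min_area - 1)
    comp_labels, n_comp = ndimage.label(binary, structure=np.ones((3, 3)))
    higher = labels_img == CLASS_HIGHER
    picks: list[Pick] = []
    for comp in range(1, n_comp + 1):
        comp_mask = comp_labels == comp
        # component vetoes: a genuine two-filament component carries almost no
        # single- or higher-class probability mass
        if probs[CLASS_SINGLE][comp_mask].mean() > params.max_single_prob:
            continue
        if probs[CLASS_HIGHER][comp_mask].mean() > params.max_higher_prob:
            continue
        skel = skeletonize(comp_mask)
        path = _skeleton_longest_path(skel)
        if len(path) < 2:
            continue
        pth = np.array(path, dtype=float)  # (n, 2) as (y, x)
        pth = _smooth_path(pth)
        pth = _extend_path_ends(pth, ndimage.distance_transform_edt(comp_mask))
        seglen = np.hypot(*np.diff(pth, axis=0).T)
        arclen = np.concatenate([[0.0], np.cumsum(seglen)])
        total = arclen[-1]
        if total < params.min_len:
            continue
        score = float(prob[comp_mask].mean())
        n_picks = int(np.floor(total / params.step))
        half_box = params.box // 2
        ny, nx = prob.shape
        for k in range(n_picks):
            s = (k + 0.5) * params.step
            i = int(np.searchsorted(arclen, s, side="right") - 1)
            i = min(i, len(pth) - 2)
            f = (s - arclen[i]) / max(arclen[i + 1] - arclen[i], 1e-9)
            y, x = pth[i] + f * (pth[i + 1] - pth[i])
            # local tangent for the axis angle
            j0, j1 = max(i - 4, 0), min(i + 5, len(pth) - 1)
            dy, dx = pth[j1] - pth[j0]
            angle = float(np.degrees(np.arctan2(dy, dx)))
            y0, y1 = max(int(y) - half_box, 0), min(int(y) + half_box + 1, ny)
            x0, x1 = max(int(x) - half_box, 0), min(int(x) + half_box + 1, nx)
            frac_higher = float(higher[y0:y1, x0:x1].mean()) if y1 > y0 and x1 > x0 else 0.0
            if frac_higher > params.higher_frac:
                continue
            picks.append(Pick(x=float(x) * scale, y=float(y) * scale,
                              score=score, component=comp, angle=angle))
    return picks


def picks_to_frame(picks: list[Pick]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"x": p.x, "y": p.y, "class": p.cls, "score": p.score,
          "angle": p.angle, "component": p.component} for p in picks],
        columns=["x", "y", "class", "score", "angle", "component"],
    )


def save_model(net: TrainedNet, path) -> None:
    """Persist a trained net (NetSpec, weights, history) as a checkpoint."""
    import joblib

    joblib.dump({"spec": net.spec, "mlp": net.mlp, "history": net.history,
                 "pixel_size": net.pixel_size}, path)


def load_model(path) -> TrainedNet:
    import joblib

    d = joblib.load(path)
    return TrainedNet(d["spec"], d["mlp"], d["history"], d["pixel_size"])


def train_picker(dataset, seed: int = 0, denoiser_epochs: int = 15,
                 segmenter_epochs: int = 25, pixel_size: float = 4.4) -> "BundlePicker":
    """Train the default denoiser + segmenter pair and wrap them in a picker."""
    den = train_denoiser(dataset, epochs=denoiser_epochs, seed=seed,
                         pixel_size=pixel_size)
    seg = train_segmenter(dataset, epochs=segmenter_epochs, seed=seed + 1,
                          denoiser=den, pixel_size=pixel_size)
    return BundlePicker(den, seg)


@dataclass
class BundlePicker:
    """End-to-end picker: denoise, segment, extract picks."""

    denoiser: TrainedNet | None
    segmenter: TrainedNet
    params: PickParams = field(default_factory=PickParams)
    stride: int = 2

    def pick(self, micrograph: Micrograph) -> tuple[pd.DataFrame, SegMask]:
        mask = infer(self.segmenter, micrograph, stride=self.stride,
                     denoiser=self.denoiser)
        scale = self.segmenter.spec.binning
        # mask is at working binning; params arrive in micrograph pixels
        picks = picks_from_mask(mask, self.params.rescaled(scale), scale=scale)
        return picks_to_frame(picks), mask


def evaluate_picks(picks: pd.DataFrame, truth_picks: pd.DataFrame,
                   truth_labels: np.ndarray, step: float = 50.0) -> dict:
    """Precision/recall of picks against ground truth.

    A pick matches an unmatched ground-truth pick within ``step/2`` pixels
    (greedy nearest-distance matching). Also reports the fraction of picks
    that land on single-filament pixels of the truth mask.
    """
    tol = step / 2.0
    n_truth = len(truth_picks)
    n_picks = len(picks)
    matched_truth = np.zeros(n_truth, dtype=bool)
    matched_pick = np.zeros(n_picks, dtype=bool)
    if n_truth and n_picks:
        px = picks[["x", "y"]].to_numpy(float)
        tx = truth_picks[["x", "y"]].to_numpy(float)
        d = np.linalg.norm(px[:, None] - tx[None], axis=2)
        pairs = np.argwhere(d <= tol)
        order = np.argsort(d[pairs[:, 0], pairs[:, 1]])
        for pi, ti in pairs[order]:
            if not matched_pick[pi] and not matched_truth[ti]:
                matched_pick[pi] = True
                matched_truth[ti] = True
    precision = matched_pick.mean() if n_picks else 0.0
    recall = matched_truth.mean() if n_truth else 0.0
    single = 0
    ny, nx = truth_labels.shape
    for _, row in picks.iterrows():
        xi = int(np.clip(round(row["x"]), 0, nx - 1))
        yi = int(np.clip(round(row["y"]), 0, ny - 1))
        if truth_labels[yi, xi] == CLASS_SINGLE:
            single += 1
    return {
        "precision": float(precision),
        "recall": float(recall),
        "n_picks": int(n_picks),
        "n_truth": int(n_truth),
        "single_fraction": float(single / n_picks) if n_picks else 0.0,
    }
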