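"""Transfer-learning-style deep radiomics from a frozen 2D convolutional net.

Each standardized slice is forwarded independently through the first ``k``
convolutional stages of a frozen backbone; stage-``k`` activations are
average-pooled over both spatial dimensions and then averaged over slices,
yielding one feature per filter at depth ``k``.  The layer depth ``k`` is a
hyperparameter of the downstream models.

The default backbone is a small fixed stack of stride-2 convolutions whose
first stage is an analytic Gabor bank (oriented band-pass filters) and whose
deeper stages are seeded, He-initialized random zero-DC filters — strong
multi-scale texture sensitivity without any weight download.  Externally
trained weights can be plugged in from an ``.npz`` file; no weights are ever
trained or updated anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .preprocessing import SliceStack

DEFAULT_STAGE_CHANNELS = (32, 64, 128, 256)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture + weight-source description of the frozen extractor.

    ``weight_init`` selects where the frozen weights come from:

    * ``"gabor-random"`` (default) — stage 1 is a fixed analytic Gabor bank
      (oriented band-pass filters, the shape trained CNN stems converge to),
      deeper stages are seeded random zero-DC filters.  Deterministic and
      download-free, with strong multi-scale texture sensitivity;
    * ``"seeded-random"`` — every stage seeded random (zero-DC for k > 1);
    * ``"external-file"`` — load all stages from an ``.npz`` file, e.g.
      weights exported from a pretrained network.
    """

    stage_channels: tuple[int, ...] = DEFAULT_STAGE_CHANNELS
    kernel_size: int = 3
    stem_kernel_size: int = 7  # gabor-random stem only
    stride: int = 2
    input_channels: int = 1
    weight_init: str = "gabor-random"
    weights_file: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_channels) < 3:
            raise ConfigurationError("backbone needs >= 3 stages")
        if any(c < 1 for c in self.stage_channels):
            raise ConfigurationError("stage channel counts must be positive")
        for k in (self.kernel_size, self.stem_kernel_size):
            if k < 1 or k % 2 == 0:
                raise ConfigurationError("kernel sizes must be odd and >= 1")
        if self.weight_init not in ("gabor-random", "seeded-random", "external-file"):
            raise ConfigurationError(f"unknown weight_init: {self.weight_init}")
        if self.weight_init == "external-file" and not self.weights_file:
            raise ConfigurationError("external-file init requires weights_file")


@dataclass
class Backbone:
    """Frozen weights: per stage a (C_out, C_in, k, k) kernel and (C_out,) bias."""

    config: BackboneConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_stages(self) -> int:
        return len(self.weights)


def gabor_bank(
    n_filters: int, c_in: int = 1, kernel_size: int = 7
) -> np.ndarray:
    """Fixed oriented band-pass (Gabor) filter bank of shape (n, c_in, k, k).

    Filters sweep a deterministic orientation x spatial-frequency grid
    (4 orientations; frequencies log-spaced over [0.07, 0.42] cycles/px),
    are zero-DC, and L2-normalized.  Replicated over input channels and
    scaled so the summed response keeps unit gain.
    """
    n_orient = 4
    n_freq = int(np.ceil(n_filters / n_orient))
    freqs = np.geomspace(0.07, 0.42, n_freq)
    xs = np.arange(kernel_size) - kernel_size // 2
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    filters = []
    for f in freqs:
        sigma = 0.56 / f  # ~one octave bandwidth
        env = np.exp(-(X**2 + Y**2) / (2.0 * sigma**2))
        for i in range(n_orient):
            theta = np.pi * i / n_orient
            xr = X * np.cos(theta) + Y * np.sin(theta)
            g = env * np.cos(2.0 * np.pi * f * xr)
            g -= g.mean()
            g /= np.sqrt((g**2).sum())
            filters.append(g)
            if len(filters) == n_filters:
                break
        if len(filters) == n_filters:
            break
    W = np.stack(filters)[:, None, :, :] / c_in
    return np.repeat(W, c_in, axis=1)


def build_backbone(config: BackboneConfig) -> Backbone:
    """Instantiate the frozen backbone, deterministic given the seed."""
    channels = (config.input_channels, *config.stage_channels)
    k = config.kernel_size
    if config.weight_init == "external-file":
        path = Path(config.weights_file)
        try:
            data = np.load(path)
            weights = [np.asarray(data[f"W{i}"], dtype=float)
                       for i in range(len(config.stage_channels))]
            biases = [np.asarray(data[f"b{i}"], dtype=float)
                      for i in range(len(config.stage_channels))]
        except (OSError, KeyError, ValueError) as exc:
            raise ConfigurationError(f"malformed weight file {path}: {exc}") from exc
        for i, (w, b) in enumerate(zip(weights, biases)):
            ok = (
                w.ndim == 4
                and w.shape[0] == channels[i + 1]
                and w.shape[1] == channels[i]
                and w.shape[2] == w.shape[3]
                and w.shape[2] % 2 == 1
                and b.shape == (channels[i + 1],)
            )
            if not ok:  # kernel size may differ per stage; channels may not
                raise ConfigurationError(
                    f"weight file stage {i}: shape {w.shape} incompatible with "
                    f"channels {channels[i]}->{channels[i + 1]}"
                )
    else:
        rng = np.random.default_rng(config.seed)
        weights, biases = [], []
        for s, (c_in, c_out) in enumerate(zip(channels[:-1], channels[1:])):
            if s == 0 and config.weight_init == "gabor-random":
                weights.append(gabor_bank(c_out, c_in, config.stem_kernel_size))
            else:
                fan_in = c_in * k * k
                W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
                if k > 1:
                    # zero-DC filters: trained early-stage filters are
                    # band-pass; without this the pooled response of a random
                    # filter is dominated by its DC gain times the slice mean,
                    # drowning the texture signal the extractor exists for
                    W -= W.mean(axis=(2, 3), keepdims=True)
                weights.append(W)
            biases.append(np.zeros(c_out))
    return Backbone(config=config, weights=weights, biases=biases)


def save_weights(backbone: Backbone, path: str | Path) -> None:
    arrays = {}
    for i, (w, b) in enumerate(zip(backbone.weights, backbone.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, **arrays)


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Same-padded strided 2D convolution; x is (C_in, H, W)."""
    k = W.shape[-1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C_in, Ho, Wo, k, k)
    out = np.einsum("cijuv,ocuv->oij", win, W, optimize=True)
    return out + b[:, None, None]


def _forward_stages(backbone: Backbone, x: np.ndarray, depth_k: int) -> list[np.ndarray]:
    """Activations after each of stages 1..depth_k for one (C_in, H, W) input."""
    acts = []
    for s in range(depth_k):
        x = _conv2d(x, backbone.weights[s], backbone.biases[s], backbone.config.stride)
        x = np.maximum(x, 0.0)  # ReLU
        acts.append(x)
    return acts


def _as_input(slice_2d: np.ndarray, c_in: int) -> np.ndarray:
    return np.repeat(slice_2d[None, :, :], c_in, axis=0)


def forward_features(backbone: Backbone, stack: SliceStack, depth_k: int) -> np.ndarray:
    """Pooled deep feature vector of length ``stage_channels[depth_k - 1]``.

    Each slice is forwarded independently through stages 1..k; activations are
    average-pooled over both spatial dimensions, then averaged over slices.
    """
    if not 1 <= depth_k <= backbone.n_stages:
        raise ConfigurationError(
            f"depth_k={depth_k} outside 1..{backbone.n_stages}"
        )
    return forward_all_pooled(backbone, stack, depth_k)[depth_k]


def _pooled(a: np.ndarray, support: np.ndarray | None, stride: int, depth: int) -> np.ndarray:
    """Average a (C, H, W) activation over space, restricted to the node support.

    The support mask is brought to the stage's resolution by the same strided
    center sampling the convolutions use.  Restricting the average to the
    node's spatial support makes pooled features invariant to how much of the
    canvas the node covers; with no support, the plain spatial mean is used.
    """
    if support is None:
        return a.mean(axis=(1, 2))
    m = support[:: stride**depth, :: stride**depth]
    m = m[: a.shape[1], : a.shape[2]]
    if m.sum() == 0:
        return a.mean(axis=(1, 2))
    return a[:, m].mean(axis=1)


def forward_all_pooled(
    backbone: Backbone, stack: SliceStack, max_depth: int | None = None
) -> dict[int, np.ndarray]:
    """Pooled feature vectors at every depth 1..max_depth in one forward pass."""
    max_depth = backbone.n_stages if max_depth is None else max_depth
    if not 1 <= max_depth <= backbone.n_stages:
        raise ConfigurationError(f"max_depth={max_depth} outside 1..{backbone.n_stages}")
    stride = backbone.config.stride
    sums: dict[int, np.ndarray] = {}
    for i, sl in enumerate(stack.slices):
        acts = _forward_stages(backbone, _as_input(sl, backbone.config.input_channels),
                               max_depth)
        sup = None if stack.support is None else stack.support[i]
        for d, a in enumerate(acts, start=1):
            sums[d] = sums.get(d, 0.0) + _pooled(a, sup, stride, d)
    n = len(stack.slices)
    return {d: s / n for d, s in sums.items()}


def deep_feature_maps(
    backbone: Backbone,
    stack: SliceStack,
    layer_index: int = 3,
    slice_index: int | None = None,
) -> list[np.ndarray]:
    """Un-pooled activation maps at ``layer_index`` for one slice.

    Channel order matches the pooled feature vector at the same depth, so map
    ``j`` visualizes feature ``deep.s{layer_index}.c{j}``.
    """
    if not 1 <= layer_index <= backbone.n_stages:
        raise ConfigurationError(f"layer_index={layer_index} outside 1..{backbone.n_stages}")
    if slice_index is None:
        slice_index = len(stack.slices) // 2
    sl = stack.slices[slice_index]
    acts = _forward_stages(backbone, _as_input(sl, backbone.config.input_channels),
                           layer_index)
    return [acts[-1][c] for c in range(acts[-1].shape[0])]


def deep_feature_names(backbone_config: BackboneConfig, depth_k: int) -> list[str]:
    return [f"deep.s{depth_k}.c{j:03d}"
            for j in range(backbone_config.stage_channels[depth_k - 1])]
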