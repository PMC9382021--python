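"""Deep feature extraction: backbone -> global average pooling -> 512-unit FC.

The contract mirrors transfer-learning radiomics: a convolutional backbone
produces feature maps, a global average pooling (GAP) layer reduces each map
to its spatial mean, and a 512-neuron fully connected layer (ReLU) yields the
deep feature vector DL_1..DL_512.  A softmax head exists but is unused in
feature mode.

Two backbones are available:

- ``tiny-test-cnn``: a small, pure-numpy two-block CNN with seeded random
  weights.  It is fully deterministic, needs no downloads, and makes the
  whole image -> features path verifiable against hand-constructed weights.
- ``resnet50``: a standard 50-layer residual network via torch, with weights
  loaded from a user-supplied file.  Optional plug-in; importing it requires
  torch to be installed.

Random weights are an established source of generic texture-sensitive
features (random-projection networks); no claim of semantic content is made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from habitomics.imaging_io import crop_resize_input, largest_roi_slice, RoiMask

N_DEEP_FEATURES = 512


@dataclass
class BackboneSpec:
    """Backbone selection and weight provenance for deep feature extraction."""

    architecture: str = "tiny-test-cnn"
    weights: object = ("random", 0)  # ("random", seed) or a path to an .npz file
    input_side: int = 224
    channels: int = 3


@dataclass
class TinyCnnWeights:
    """Explicit weights of the tiny test CNN (two conv blocks + FC head)."""

    conv1: np.ndarray  # (8, 3, 3, 3)   out_ch, in_ch, kh, kw
    bias1: np.ndarray  # (8,)
    conv2: np.ndarray  # (16, 8, 3, 3)
    bias2: np.ndarray  # (16,)
    fc_w: np.ndarray  # (512, 16)
    fc_b: np.ndarray  # (512,)
    softmax_w: np.ndarray = None  # type: ignore[assignment]  # (n_classes, 512)
    softmax_b: np.ndarray = None  # type: ignore[assignment]

    @classmethod
    def random(cls, seed: int, n_classes: int = 2) -> "TinyCnnWeights":
        rng = np.random.default_rng(seed)

        def glorot(shape):
            fan = np.prod(shape[1:]) + shape[0]
            return rng.normal(0.0, np.sqrt(2.0 / fan), size=shape)

        return cls(
            conv1=glorot((8, 3, 3, 3)),
            bias1=np.zeros(8),
            conv2=glorot((16, 8, 3, 3)),
            bias2=np.zeros(16),
            fc_w=glorot((N_DEEP_FEATURES, 16)),
            fc_b=np.zeros(N_DEEP_FEATURES),
            softmax_w=glorot((n_classes, N_DEEP_FEATURES)),
            softmax_b=np.zeros(n_classes),
        )

    def save(self, path) -> None:
        np.savez(
            path,
            conv1=self.conv1,
            bias1=self.bias1,
            conv2=self.conv2,
            bias2=self.bias2,
            fc_w=self.fc_w,
            fc_b=self.fc_b,
            softmax_w=self.softmax_w,
            softmax_b=self.softmax_b,
        )

    @classmethod
    def load(cls, path) -> "TinyCnnWeights":
        with np.load(path) as z:
            return cls(**{k: z[k] for k in z.files})


def gap(feature_maps: np.ndarray) -> np.ndarray:
    """Global average pooling: the spatial mean of each feature map.

    ``feature_maps`` has shape (n_maps, h, w); the result has length n_maps.
    """
    fm = np.asarray(feature_maps, dtype=np.float64)
    if fm.ndim != 3 or fm.shape[0] == 0 or fm.shape[1] == 0 or fm.shape[2] == 0:
        raise ValueError("gap expects a non-empty (n_maps, h, w) stack")
    return fm.mean(axis=(1, 2))


def _conv2d_bank(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """'same' multi-channel 2-D convolution: (in_ch,h,w) -> (out_ch,h,w)."""
    out_ch = kernels.shape[0]
    out = np.empty((out_ch,) + x.shape[1:])
    for o in range(out_ch):
        acc = np.zeros(x.shape[1:])
        for i in range(x.shape[0]):
            acc += ndimage.correlate(x[i], kernels[o, i], mode="constant", cval=0.0)
        out[o] = acc + bias[o]
    return out


def _avgpool(x: np.ndarray, k: int) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // k, w // k
    return x[:, : h2 * k, : w2 * k].reshape(c, h2, k, w2, k).mean(axis=(2, 4))


def _normalize_input(image: np.ndarray, channels: int) -> np.ndarray:
    """Per-image min-max to [0, 1], replicated to the channel count."""
    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return np.repeat(img[None], channels, axis=0)


def _tiny_forward(weights: TinyCnnWeights, image: np.ndarray, channels: int = 3) -> np.ndarray:
    """tiny-test-cnn forward pass: conv-relu-pool x2 -> GAP -> FC(512)+ReLU."""
    x = _normalize_input(image, channels)
    x = np.maximum(_conv2d_bank(x, weights.conv1, weights.bias1), 0.0)
    x = _avgpool(x, 8)
    x = np.maximum(_conv2d_bank(x, weights.conv2, weights.bias2), 0.0)
    x = _avgpool(x, 2)
    pooled = gap(x)
    fc = weights.fc_w @ pooled + weights.fc_b
    return np.maximum(fc, 0.0)


def _resolve_tiny_weights(spec: BackboneSpec) -> TinyCnnWeights:
    w = spec.weights
    if isinstance(w, TinyCnnWeights):
        return w
    if isinstance(w, tuple) and len(w) == 2 and w[0] == "random":
        return TinyCnnWeights.random(int(w[1]))
    try:
        return TinyCnnWeights.load(w)
    except FileNotFoundError:
        raise FileNotFoundError(f"weight file not found: {w}")


def extract(spec: BackboneSpec, image: np.ndarray) -> dict:
    """Deep feature vector DL_1..DL_512 for one prepared input image.

    ``image`` is a 2-D ``input_side x input_side`` array (single channel,
    replicated internally) as produced by
    :func:`~habitomics.imaging_io.crop_resize_input`.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (spec.input_side, spec.input_side):
        raise ValueError(
            f"expected a {spec.input_side}x{spec.input_side} input, got {image.shape}"
        )
    if spec.architecture == "tiny-test-cnn":
        feats = _tiny_forward(_resolve_tiny_weights(spec), image, spec.channels)
    elif spec.architecture == "resnet50":
        feats = _resnet50_forward(spec, image)
    else:
        raise ValueError(f"unknown backbone architecture {spec.architecture!r}")
    if len(feats) != N_DEEP_FEATURES or not np.all(np.isfinite(feats)):
        raise RuntimeError("backbone produced an invalid feature vector")
    return {f"DL_{i + 1}": float(v) for i, v in enumerate(feats)}


def _resnet50_forward(spec: BackboneSpec, image: np.ndarray) -> np.ndarray:
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - optional plug-in
        raise ImportError(
            "the resnet50 backbone requires torch/torchvision; "
            "use architecture='tiny-test-cnn' or install them"
        ) from exc
    # pragma: no cover - exercised only when torch is installed
    model = torchvision.models.resnet50()
    state = torch.load(spec.weights, map_location="cpu", weights_only=True)
    model.load_state_dict(state, strict=False)
    backbone = torch.nn.Sequential(*list(model.children())[:-2])
    backbone.eval()
    fc = torch.nn.Linear(2048, N_DEEP_FEATURES)
    torch.manual_seed(0)
    with torch.no_grad():
        x = torch.from_numpy(_normalize_input(image, spec.channels)[None]).float()
        maps = backbone(x)[0].numpy()
        pooled = gap(maps)
        feats = torch.relu(fc(torch.from_numpy(pooled).float())).numpy()
    return feats.astype(np.float64)


def extract_cohort(
    cases,
    partition,
    subregion: str = "S1",
    spec: BackboneSpec | None = None,
    masks: dict | None = None,
) -> dict:
    """Deep features of the largest subregion slice, per case.

    For each case the axial slice with the largest subregion area is cropped,
    masked and resized, then passed through the backbone.  Cases whose
    subregion is empty (or absent under an alternative mask set) are skipped
    with a warning.  ``masks`` optionally substitutes per-case ROI masks (e.g.
    a second observer's segmentation); the subregion is then the intersection
    of the partition's subregion labels with that mask.

    Returns ``{case_id: {DL_1: ..., ..., DL_512: ...}}``.
    """
    if spec is None:
        spec = BackboneSpec()
    rank = int(subregion[1:])
    out = {}
    for case in cases:
        sub = partition.labels[case.case_id] == rank
        if masks is not None:
            sub = sub & (masks[case.case_id].data != 0)
        if not sub.any():
            warnings.warn(f"{case.case_id}: subregion {subregion} empty, skipped", stacklevel=2)
            continue
        z = largest_roi_slice(RoiMask(data=sub))
        img224 = crop_resize_input(
            case.volume.data[:, :, z], sub[:, :, z], side=spec.input_side
        )
        out[case.case_id] = extract(spec, img224)
    return out
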