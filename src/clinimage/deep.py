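"""Frozen convolutional feature extraction (AlexNet prefix to pool2).

Patient images are resized to 227x227, replicated to 3 channels and passed
through the fixed AlexNet front end

    conv1 96@11x11 stride 4 -> ReLU -> maxpool 3x3 stride 2
    conv2 256@5x5 pad 2     -> ReLU -> maxpool 3x3 stride 2

whose pool2 output is 13x13x256, flattened channel-major into a 43,264-length
feature vector per patient. The network is a pure feature extractor — never
trained here — so the forward pass is implemented directly in numpy (batched
im2col + BLAS matmul); no deep-learning runtime is required. Weights are
drawn from a seeded He-normal initialiser so extraction is fully reproducible
offline; requesting pretrained weights raises (no network at run time).

Shape arithmetic, asserted programmatically at build time:
227 -(conv 11, s4)-> 55 -(pool 3, s2)-> 27 -(conv 5, p2)-> 27 -(pool 3, s2)-> 13.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _skimage_resize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExtractorSpec",
    "DeepFeatureMatrix",
    "WeightsUnavailableError",
    "resize_to_input",
    "extract",
    "Pool2FeatureExtractor",
    "POOL2_LENGTH",
]

INPUT_SIZE = 227
POOL2_SHAPE = (256, 13, 13)  # channel, row, col
POOL2_LENGTH = int(np.prod(POOL2_SHAPE))  # 43,264


class WeightsUnavailableError(RuntimeError):
    """Pretrained weights were requested but cannot be loaded offline."""


@dataclass(frozen=True)
class ExtractorSpec:
    """Extractor configuration: weight source and input size (fixed at 227)."""

    weights_source: str = "seeded-random"  # or "pretrained"
    seed: int = 0
    input_size: int = INPUT_SIZE

    def __post_init__(self) -> None:
        if self.weights_source not in ("seeded-random", "pretrained"):
            raise ValueError(f"unknown weights_source {self.weights_source!r}")
        if self.input_size != INPUT_SIZE:
            raise ValueError("the architecture is fixed to 227x227 inputs")


@dataclass
class DeepFeatureMatrix:
    """n x 43,264 pool2 activations plus a digest of the weights used."""

    values: np.ndarray
    extractor_fingerprint: str

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != POOL2_LENGTH:
            raise ValueError(f"expected {POOL2_LENGTH} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite activations")


def _out_size(n: int, k: int, stride: int, pad: int = 0) -> int:
    return (n + 2 * pad - k) // stride + 1

# conv1 -> pool1 -> conv2 -> pool2 spatial sizes
_S1 = _out_size(INPUT_SIZE, 11, 4)          # 55
_S2 = _out_size(_S1, 3, 2)                  # 27
_S3 = _out_size(_S2, 5, 1, pad=2)           # 27
_S4 = _out_size(_S3, 3, 2)                  # 13
assert (_S1, _S2, _S3, _S4) == (55, 27, 27, 13)
assert POOL2_SHAPE == (256, _S4, _S4)


def resize_to_input(image: np.ndarray) -> np.ndarray:
    """Bilinearly resize a grayscale grid to 227x227 and replicate to 3
    channels; output shape (3, 227, 227), same value range as the input."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2D grayscale image")
    resized = _skimage_resize(
        img, (INPUT_SIZE, INPUT_SIZE), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.repeat(resized[None, :, :], 3, axis=0)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _init_weights(seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    return {
        "conv1_w": _he_normal(rng, (96, 3, 11, 11)),
        "conv1_b": np.zeros(96, dtype=np.float32),
        "conv2_w": _he_normal(rng, (256, 96, 5, 5)),
        "conv2_b": np.zeros(256, dtype=np.float32),
    }


def _fingerprint(weights: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(weights):
        h.update(key.encode())
        h.update(np.ascontiguousarray(weights[key]).tobytes())
    return h.hexdigest()[:16]


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
            stride: int, pad: int) -> np.ndarray:
    """Batched 2D convolution via im2col; x is (n, c, h, w), w is (o, c, k, k)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    k = w.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, oh, ow, k, k)
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(n, oh, ow, w.shape[0]).transpose(0, 3, 1, 2)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride].max(axis=(4, 5))


def _forward_pool2(batch: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    x = batch.astype(np.float32)
    x = np.maximum(_conv2d(x, weights["conv1_w"], weights["conv1_b"], 4, 0), 0.0)
    x = _maxpool(x)
    x = np.maximum(_conv2d(x, weights["conv2_w"], weights["conv2_b"], 1, 2), 0.0)
    x = _maxpool(x)
    return x  # (n, 256, 13, 13)


def extract(
    images: np.ndarray | list[np.ndarray],
    spec: ExtractorSpec = ExtractorSpec(),
    batch_size: int = 16,
) -> DeepFeatureMatrix:
    """Extract pool2 feature vectors from grayscale patient images.

    ``images`` is an (n, rows, cols) stack (or list of 2D arrays) with values
    in [0, 1]. Flattening is channel-major (channel, then row, then column),
    fixed across runs.
    """
    if spec.weights_source == "pretrained":
        raise WeightsUnavailableError(
            "pretrained weights are not bundled and cannot be downloaded here; "
            "use weights_source='seeded-random'"
        )
    weights = _init_weights(spec.seed)
    stack = [resize_to_input(img) for img in images]
    if not stack:
        raise ValueError("no images to extract from")
    tensors = np.stack(stack)
    feats = np.empty((len(tensors), POOL2_LENGTH), dtype=np.float32)
    for start in range(0, len(tensors), batch_size):
        block = tensors[start : start + batch_size]
        feats[start : start + len(block)] = _forward_pool2(
            block, weights
        ).reshape(len(block), POOL2_LENGTH)
    return DeepFeatureMatrix(values=feats, extractor_fingerprint=_fingerprint(weights))


class Pool2FeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style wrapper over :func:`extract`.

    ``fit`` only materialises the seeded weights (nothing is learned from the
    data); ``transform`` maps an (n, rows, cols) image stack to an
    (n, 43264) feature matrix.
    """

    def __init__(self, weights_source: str = "seeded-random", seed: int = 0,
                 batch_size: int = 16):
        self.weights_source = weights_source
        self.seed = seed
        self.batch_size = batch_size

    def fit(self, X=None, y=None) -> "Pool2FeatureExtractor":
        spec = ExtractorSpec(self.weights_source, self.seed)
        if spec.weights_source == "pretrained":
            raise WeightsUnavailableError(
                "pretrained weights unavailable offline; use 'seeded-random'"
            )
        self.weights_ = _init_weights(spec.seed)
        self.fingerprint_ = _fingerprint(self.weights_)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        tensors = np.stack([resize_to_input(img) for img in X])
        feats = np.empty((len(tensors), POOL2_LENGTH), dtype=np.float32)
        for start in range(0, len(tensors), self.batch_size):
            block = tensors[start : start + self.batch_size]
            feats[start : start + len(block)] = _forward_pool2(
                block, self.weights_
            ).reshape(len(block), POOL2_LENGTH)
        return feats
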