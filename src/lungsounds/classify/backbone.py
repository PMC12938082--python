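"""Convolutional feature extractors for 256x256x3 time-frequency images.

The default backbone is a small fixed-weight convolutional network generated
deterministically from a seed: five 3x3 stride-2 convolution + ReLU stages
taking a 256x256x3 image to an 8x8x64 feature map. Fixed random convolutional
features are a classic, download-free feature extractor that works well when
the classes differ in coarse spectro-temporal layout, which the lung-sound
representations do by design; the backbone is always frozen.

Pretrained ImageNet backbones (DenseNet201, VGG16/19, InceptionV3,
MobileNetV2, ResNet50V2) can be plugged in behind the same
:class:`BackboneSpec` contract by registering a feature function; none are
bundled, since they require weight downloads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class BackboneSpec:
    """Contract a feature extractor must satisfy.

    ``trainable_top_layers = 0`` means fully frozen (the only mode of the
    bundled backbone); ``feature_map_shape`` is the (H, W, C) of the final
    convolutional block.
    """

    name: str = "tiny"
    trainable_top_layers: int = 0
    feature_map_shape: tuple[int, int, int] = (8, 8, 64)

    def __post_init__(self) -> None:
        if self.trainable_top_layers < 0:
            raise ValueError("trainable_top_layers must be >= 0")
        h, w, c = self.feature_map_shape
        if h < 1 or w < 1 or c < 1:
            raise ValueError("feature_map_shape entries must be >= 1")


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int = 2) -> np.ndarray:
    """3x3 'same'-padded strided convolution via im2col + matmul.

    x: (N, H, W, Cin); w: (3, 3, Cin, Cout) -> (N, H//stride, W//stride, Cout).
    """
    n, h, wd, cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (N, Ho, Wo, Cin, 3, 3)
    ho, wo = win.shape[1], win.shape[2]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, 9 * cin)
    kern = w.reshape(9 * cin, -1)
    return (cols @ kern).reshape(n, ho, wo, -1)


class TinyConvBackbone:
    """Frozen five-stage random convolutional feature extractor.

    Weights are He-scaled Gaussians drawn once from ``seed``; the extractor
    is bit-deterministic and identical across processes.
    """

    CHANNELS = (16, 32, 64, 64, 64)

    def __init__(self, seed: int = 12345):
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        cin = 3
        for cout in self.CHANNELS:
            std = np.sqrt(2.0 / (9 * cin))
            self.weights.append(rng.normal(0.0, std, size=(3, 3, cin, cout)))
            cin = cout
        self.spec = BackboneSpec(name="tiny", trainable_top_layers=0, feature_map_shape=(8, 8, 64))

    def features(self, images: np.ndarray) -> np.ndarray:
        """Feature maps for a batch of (N, 256, 256, 3) images in [0, 1]."""
        x = np.asarray(images, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.shape[1:] != (256, 256, 3):
            raise ValueError(f"expected (N, 256, 256, 3) images, got {x.shape}")
        for w in self.weights:
            x = np.maximum(_conv2d(x, w, stride=2), 0.0)
        return x[0] if single else x

    def weights_hash(self) -> str:
        """Digest of all weights — lets tests prove the backbone never trains."""
        h = hashlib.sha256()
        for w in self.weights:
            h.update(w.tobytes())
        return h.hexdigest()


_REGISTRY: dict[str, Callable[[], "TinyConvBackbone"]] = {"tiny": TinyConvBackbone}


def register_backbone(name: str, factory: Callable[[], object]) -> None:
    """Register a pluggable backbone factory (e.g. a pretrained network wrapper)."""
    _REGISTRY[name] = factory


def get_backbone(name: str = "tiny"):
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; registered: {list(_REGISTRY)}")


def extract_feature_map(image: np.ndarray, backbone=None) -> np.ndarray:
    """Feature map of one normalized image from the (frozen) backbone.

    Raises on shape mismatch with the backbone's declared input/output.
    """
    backbone = backbone or TinyConvBackbone()
    fmap = backbone.features(image)
    expected = backbone.spec.feature_map_shape
    got = fmap.shape[-3:]
    if tuple(got) != tuple(expected):
        raise ValueError(f"feature map shape {got} != declared {expected}")
    return fmap
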