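"""Tile feature extractors.

The default ``small_cnn`` backbone is a three-block convolutional network
sized for CPU training on desk-scale slides: two frozen blocks act as a
fixed texture filter bank (their weights are package constants, playing the
role a pretrained network's early layers play at full scale) and the third
block is trainable, mirroring the common fine-tuning setup where all but
the last convolutional layer stay frozen.  Global average pooling yields a
64-dimensional tile feature.

A ``resnet50_imagenet`` mode (frozen pretrained ResNet-50, D=2048) is part
of the configuration surface but cannot be constructed here: pretrained
weights cannot ship inside this source-only package, so requesting it
raises :class:`BackboneUnavailableError`.
"""

from __future__ import annotations

import numpy as np

from ..errors import BackboneUnavailableError
from . import nn

#: Fixed seed for the frozen filter bank: a package constant, not a knob.
_FROZEN_SEED = 74120457

SMALL_CNN_FEATURE_DIM = 64


class SmallCNN:
    """3-block CNN: conv3x3(3->8)/pool4, conv3x3(8->16)/pool8 frozen; conv3x3(16->64) trainable."""

    feature_dim = SMALL_CNN_FEATURE_DIM

    def __init__(self, seed: int = 0) -> None:
        frozen_rng = np.random.default_rng(np.random.SeedSequence([_FROZEN_SEED]))
        self.frozen = {
            "w1": nn.he_init(frozen_rng, 27, (27, 8)).astype(np.float32),
            "b1": np.zeros(8, dtype=np.float32),
            "w2": nn.he_init(frozen_rng, 72, (72, 16)).astype(np.float32),
            "b2": np.zeros(16, dtype=np.float32),
        }
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
        self.trainable = {
            "w3": nn.he_init(rng, 144, (144, 64)).astype(np.float32),
            "b3": np.zeros(64, dtype=np.float32),
        }

    # -- frozen prefix ---------------------------------------------------

    def forward_prefix(self, x: np.ndarray) -> np.ndarray:
        """(N, 256, 256, 3) standardized float -> (N, 8, 8, 16) frozen features."""
        h = nn.relu(nn.conv3x3(x, self.frozen["w1"], self.frozen["b1"]))
        h = nn.maxpool(h, 4)
        h = nn.relu(nn.conv3x3(h, self.frozen["w2"], self.frozen["b2"]))
        return nn.maxpool(h, 8)

    # -- trainable tail --------------------------------------------------

    def forward_trainable(self, prefix: np.ndarray, want_cache: bool = False):
        """(N, 8, 8, 16) -> (N, 64) tile features via conv + ReLU + global average pool."""
        cols = nn.im2col3x3(prefix)                     # (N, 8, 8, 144)
        pre = cols @ self.trainable["w3"] + self.trainable["b3"]
        act = nn.relu(pre)
        feat = act.mean(axis=(1, 2))
        if want_cache:
            return feat, (cols, pre)
        return feat

    def backward_trainable(self, dfeat: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the trainable conv from per-tile feature gradients."""
        cols, pre = cache
        n, h, w, _ = pre.shape
        dact = np.broadcast_to(dfeat[:, None, None, :], pre.shape) / (h * w)
        dpre = np.where(pre > 0, dact, 0.0)
        flat_cols = cols.reshape(-1, cols.shape[-1])
        flat_dpre = dpre.reshape(-1, dpre.shape[-1])
        return {
            "w3": flat_cols.T @ flat_dpre,
            "b3": flat_dpre.sum(axis=0),
        }

    def frozen_bytes(self) -> bytes:
        """Byte snapshot of the frozen parameters (for conservation checks)."""
        return b"".join(self.frozen[k].tobytes() for k in sorted(self.frozen))


def make_backbone(name: str, seed: int = 0) -> SmallCNN:
    if name == "small_cnn":
        return SmallCNN(seed=seed)
    if name == "resnet50_imagenet":
        raise BackboneUnavailableError(
            "the resnet50_imagenet backbone requires pretrained weights that "
            "cannot ship with this package; use backbone='small_cnn'"
        )
    raise BackboneUnavailableError(f"unknown backbone {name!r}")
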