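"""The patch classification network.

A LeNet-style stack for 32x32 grayscale patches: three 3x3 convolution
blocks (128, 64, 32 filters; each convolution followed by ReLU and local
response normalization, stride 1, padding 1, so the spatial size stays
32x32) and three fully connected layers (32*32*32 -> 4096 -> 1024 -> 2)
ending in a 2-way softmax.  The class-1 probability is the network's
estimate that the choroidal-scleral interface passes through the patch's
recognition area.

``width_scale`` scales every channel / hidden width (the "tiny"
configuration halves them) so the same architecture trains at desk scale
on one CPU; full widths remain available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import LRN, Conv3x3, Dense, Flatten, Layer, ReLU, softmax

CONV_CHANNELS = (128, 64, 32)
FC_SIZES = (4096, 1024)
PATCH = 32
N_CLASSES = 2


@dataclass(frozen=True)
class ArchConfig:
    width_scale: float = 1.0

    @property
    def conv_channels(self) -> tuple:
        return tuple(max(1, int(round(c * self.width_scale))) for c in CONV_CHANNELS)

    @property
    def fc_sizes(self) -> tuple:
        return tuple(max(1, int(round(f * self.width_scale))) for f in FC_SIZES)


class PatchCNN:
    """Forward/backward network over (B, 32, 32) patches scaled to [0, 1]."""

    def __init__(self, arch: ArchConfig = ArchConfig(), seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c1, c2, c3 = arch.conv_channels
        f1, f2 = arch.fc_sizes
        self.layers: list[Layer] = [
            Conv3x3(1, c1, rng, dtype, first=True), ReLU(), LRN(),
            Conv3x3(c1, c2, rng, dtype), ReLU(), LRN(),
            Conv3x3(c2, c3, rng, dtype), ReLU(), LRN(),
            Flatten(),
            Dense(PATCH * PATCH * c3, f1, rng, dtype), ReLU(),
            Dense(f1, f2, rng, dtype), ReLU(),
            Dense(f2, N_CLASSES, rng, dtype),
        ]

    # ---- parameter access -------------------------------------------------

    def parameters(self):
        """Yield (key, layer, name) triples addressing every trainable array."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}.{name}", layer, name

    def param_vector_sq_norm(self) -> float:
        return float(sum(np.sum(l.params[n].astype(np.float64) ** 2) for _, l, n in self.parameters()))

    # ---- forward / backward ----------------------------------------------

    def logits(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(patches, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1:] != (PATCH, PATCH):
            raise ValueError(f"expected (B, {PATCH}, {PATCH}) patches, got {x.shape}")
        x = x[..., None]  # channels-last
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        g = np.asarray(dlogits, dtype=self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-1 probability for each patch, computed in batches."""
        patches = np.asarray(patches, dtype=self.dtype)
        out = np.empty(len(patches), dtype=np.float64)
        for s in range(0, len(patches), batch_size):
            z = self.logits(patches[s : s + batch_size])
            out[s : s + batch_size] = softmax(z.astype(np.float64))[:, 1]
        return out

    # ---- serialization ----------------------------------------------------

    def state_dict(self) -> dict:
        return {k: l.params[n].copy() for k, l, n in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for k, l, n in self.parameters():
            if l.params[n].shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            l.params[n] = state[k].astype(self.dtype)
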