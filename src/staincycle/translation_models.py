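"""Generator / discriminator topologies and class-label conditioning.

The generator is an encoder-bottleneck-decoder stack: a 7x7 stem, two
stride-2 downsampling convs, two 3x3 bottleneck convs at 256 channels (the
second ends at its InstanceNorm with no activation, kept verbatim as a plain
sequence rather than a residual block), two stride-2 transposed convs back
up, and a 7x7 head into Tanh. The discriminator is a 7x7 stem + three
stride-2 convs with LeakyReLU(0.2), a k=4 conv to one channel and a global
average pool to a single scalar score per image.

Class conditioning appends one spatially constant plane to the generator
input (+1 tumour, -1 normal, matching the [-1, 1] pixel normalization);
discriminators always see plain 3-channel images.

A width multiplier scales all hidden channel counts for desk-scale runs;
1.0 reproduces the reference topology exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .config import NORMAL_LABEL, TUMOR_LABEL

LABEL_ENCODING = {TUMOR_LABEL: 1.0, NORMAL_LABEL: -1.0}


def _c(width: float, channels: int) -> int:
    return max(1, int(round(channels * width)))


def build_generator(conditioned: bool = True, width: float = 1.0,
                    rng: np.random.Generator | None = None,
                    residual: bool = False) -> nn.Sequential:
    """Generator network; ``conditioned`` adds the label input channel.

    ``residual=True`` swaps the plain two-conv bottleneck for a ResNet-style
    skip join (the topology table is ambiguous there); default is the literal
    plain sequence.
    """
    rng = rng or np.random.default_rng(0)
    in_c = 4 if conditioned else 3
    c64, c128, c256 = _c(width, 64), _c(width, 128), _c(width, 256)
    bottleneck: list[nn.Layer] = [
        nn.Conv2d(c256, c256, k=3, s=1, p=1, rng=rng),
        nn.InstanceNorm2d(c256),
        nn.ReLU(),
        nn.Conv2d(c256, c256, k=3, s=1, p=1, rng=rng),
        nn.InstanceNorm2d(c256),
    ]
    if residual:
        bottleneck = [_ResidualBlock(nn.Sequential(*bottleneck))]
    return nn.Sequential(
        nn.Conv2d(in_c, c64, k=7, s=1, p=3, rng=rng),
        nn.InstanceNorm2d(c64),
        nn.ReLU(),
        nn.Conv2d(c64, c128, k=3, s=2, p=1, rng=rng),
        nn.InstanceNorm2d(c128),
        nn.ReLU(),
        nn.Conv2d(c128, c256, k=3, s=2, p=1, rng=rng),
        nn.InstanceNorm2d(c256),
        nn.ReLU(),
        *bottleneck,
        nn.ConvTranspose2d(c256, c128, k=3, s=2, p=1, op=1, rng=rng),
        nn.InstanceNorm2d(c128),
        nn.ReLU(),
        nn.ConvTranspose2d(c128, c64, k=3, s=2, p=1, op=1, rng=rng),
        nn.InstanceNorm2d(c64),
        nn.ReLU(),
        nn.Conv2d(c64, 3, k=7, s=1, p=3, rng=rng),
        nn.Tanh(),
    )


class _ResidualBlock(nn.Layer):
    """y = x + body(x); optional alternative bottleneck."""

    def __init__(self, body: nn.Sequential) -> None:
        super().__init__()
        self.body = body
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.body.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy + self.body.backward(gy)

    def zero_grad(self) -> None:
        self.body.zero_grad()

    def clear_cache(self) -> None:
        self.body.clear_cache()

    def named_parameters(self) -> list[tuple[nn.Layer, str]]:
        return self.body.named_parameters()


def build_discriminator(width: float = 1.0,
                        rng: np.random.Generator | None = None) -> nn.Sequential:
    """Discriminator network; scalar output per image (global average pool)."""
    rng = rng or np.random.default_rng(0)
    c64, c128, c256, c512 = (_c(width, 64), _c(width, 128),
                             _c(width, 256), _c(width, 512))
    return nn.Sequential(
        nn.Conv2d(3, c64, k=7, s=1, p=3, rng=rng),
        nn.LeakyReLU(0.2),
        nn.Conv2d(c64, c128, k=3, s=2, p=1, rng=rng),
        nn.InstanceNorm2d(c128),
        nn.LeakyReLU(0.2),
        nn.Conv2d(c128, c256, k=3, s=2, p=1, rng=rng),
        nn.InstanceNorm2d(c256),
        nn.LeakyReLU(0.2),
        nn.Conv2d(c256, c512, k=3, s=2, p=1, rng=rng),
        nn.InstanceNorm2d(c512),
        nn.LeakyReLU(0.2),
        nn.Conv2d(c512, 1, k=4, s=1, p=1, rng=rng),
        nn.GlobalAvgPool2d(),
    )


def condition(patch: np.ndarray, label: str) -> np.ndarray:
    """Append a constant label plane to a normalized (3, H, W) or (N, 3, H, W)
    patch: +1 for TUMOR, -1 for NORMAL; channel order (R, G, B, label)."""
    if label not in LABEL_ENCODING:
        raise ValueError(f"unknown label {label!r}")
    value = LABEL_ENCODING[label]
    if patch.ndim == 3:
        plane = np.full((1, *patch.shape[1:]), value, dtype=patch.dtype)
        return np.concatenate([patch, plane], axis=0)
    if patch.ndim == 4:
        plane = np.full((patch.shape[0], 1, *patch.shape[2:]), value,
                        dtype=patch.dtype)
        return np.concatenate([patch, plane], axis=1)
    raise ValueError(f"expected (3,H,W) or (N,3,H,W), got {patch.shape}")


def condition_batch(patches: np.ndarray, labels: list[str]) -> np.ndarray:
    """Per-sample conditioning of a normalized (N, 3, H, W) batch."""
    if len(labels) != patches.shape[0]:
        raise ValueError("one label per patch required")
    values = np.array([LABEL_ENCODING[l] for l in labels], dtype=patches.dtype)
    plane = np.broadcast_to(values[:, None, None, None],
                            (patches.shape[0], 1, *patches.shape[2:])).copy()
    return np.concatenate([patches, plane], axis=1)


def strip_label_channel(patch: np.ndarray) -> np.ndarray:
    """Inverse of :func:`condition`: drop the 4th channel."""
    axis = 0 if patch.ndim == 3 else 1
    return np.take(patch, [0, 1, 2], axis=axis)


def normalize(pixels: np.ndarray) -> np.ndarray:
    """uint8 (..., H, W, 3) image(s) -> float32 (..., 3, H, W) in [-1, 1]."""
    x = pixels.astype(nn.DTYPE) / 127.5 - 1.0
    if x.ndim == 3:
        return np.transpose(x, (2, 0, 1))
    return np.transpose(x, (0, 3, 1, 2))


def denormalize(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`, back to uint8 (..., H, W, 3)."""
    if x.ndim == 3:
        x = np.transpose(x, (1, 2, 0))
    else:
        x = np.transpose(x, (0, 2, 3, 1))
    return np.clip(np.round((x + 1.0) * 127.5), 0, 255).astype(np.uint8)


@dataclass
class TranslationNets:
    """The two generators and two discriminators of the cycle framework."""

    g_he_to_ki67: nn.Sequential
    g_ki67_to_he: nn.Sequential
    d_he: nn.Sequential
    d_ki67: nn.Sequential
    conditioned: bool = True
    width: float = 1.0

    @classmethod
    def create(cls, conditioned: bool = True, width: float = 1.0,
               seed: int = 0, residual: bool = False) -> "TranslationNets":
        rng = np.random.default_rng(seed)
        return cls(
            g_he_to_ki67=build_generator(conditioned, width, rng, residual),
            g_ki67_to_he=build_generator(conditioned, width, rng, residual),
            d_he=build_discriminator(width, rng),
            d_ki67=build_discriminator(width, rng),
            conditioned=conditioned, width=width)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in ("g_he_to_ki67", "g_ki67_to_he", "d_he", "d_ki67"):
            np.savez(out_dir / f"{name}.npz", **getattr(self, name).state_arrays())
        meta = {"conditioned": self.conditioned, "width": self.width,
                "n_parameters": {
                    "generator": self.g_he_to_ki67.n_parameters(),
                    "discriminator": self.d_he.n_parameters()}}
        (out_dir / "nets.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, out_dir: str | Path) -> "TranslationNets":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "nets.json").read_text())
        nets = cls.create(conditioned=meta["conditioned"], width=meta["width"])
        for name in ("g_he_to_ki67", "g_ki67_to_he", "d_he", "d_ki67"):
            with np.load(out_dir / f"{name}.npz") as data:
                getattr(nets, name).load_state_arrays({k: data[k] for k in data.files})
        return nets
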