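"""Sinogram-inpainting GAN architecture: U-Net generator, patch discriminator.

The generator is a 9-down / 9-up U-Net (configurable depth for desk-scale
instances): 4x4 stride-2 convolutions with encoder channels
64-128-256-512x6, leaky-ReLU (slope 0.2) activations, mirrored 4x4 stride-2
transposed convolutions with skip concatenations, batch normalisation on all
but the outermost layers, dropout in the first three decoder layers as the
noise source z, and a sigmoid 1x1 output head keeping estimates in the [0, 1]
sinogram range.

The discriminator is fully convolutional: five 4x4 layers with 64/128/256/512/1
filters and strides 2/2/2/1/1, plain ReLU activations and a final sigmoid, so
it emits an N x N map of per-patch real/fake probabilities whose mean is the
decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, Layer,
                 LeakyReLU, Param, ReLU, Sigmoid)

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "ModelParams",
    "UNetGenerator", "PatchDiscriminator",
    "build_generator", "build_discriminator",
    "discriminator_decision", "count_parameters",
    "save_checkpoint", "load_checkpoint",
]

ENCODER_PATTERN = (64, 128, 256, 512, 512, 512, 512, 512, 512)


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of the U-Net sinogram inpainter."""

    input_size: tuple[int, int] = (512, 512)
    depth: int = 9
    kernel: int = 4
    stride: int = 2
    leaky_slope: float = 0.2
    noise_mode: str = "dropout"      # {"dropout", "none"}
    dropout_p: float = 0.5
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.depth <= len(ENCODER_PATTERN)):
            raise ValueError("depth must lie in 1..9")
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input size {self.input_size} must be divisible by "
                f"2^depth = {1 << self.depth}; reduce depth for small instances")
        if self.noise_mode not in ("dropout", "none"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return ENCODER_PATTERN[:self.depth]

    @property
    def decoder_channels(self) -> tuple[int, ...]:
        return tuple(reversed(self.encoder_channels))


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Architecture of the patch discriminator (conditioned pair input)."""

    input_size: tuple[int, int] = (512, 512)
    in_channels: int = 2             # (conditioning, candidate) concatenated
    channels: tuple[int, ...] = (64, 128, 256, 512, 1)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    kernel: int = 4
    patch_size: int = 64
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")
        if self.patch_map_size()[0] < 1 or self.patch_map_size()[1] < 1:
            raise ValueError(
                f"input {self.input_size} too small for {len(self.channels)} "
                "discriminator layers")

    def patch_map_size(self) -> tuple[int, int]:
        h, w = self.input_size
        for s in self.strides:
            h = (h + 2 - self.kernel) // s + 1
            w = (w + 2 - self.kernel) // s + 1
        return h, w


@dataclass
class ModelParams:
    """Exact per-layer ledger of trainable scalars."""

    per_layer: list[tuple[str, tuple, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.per_layer)

    def summary(self) -> str:
        lines = [f"{name:40s} {str(shape):24s} {n:>12,d}"
                 for name, shape, n in self.per_layer]
        lines.append(f"{'total':40s} {'':24s} {self.total:>12,d}")
        return "\n".join(lines)


class _Block:
    """An ordered run of layers sharing one forward/backward sweep."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self) -> list[Param]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out


class _Model:
    blocks: list[_Block]

    def params(self) -> list[Param]:
        out = []
        for blk in self.blocks:
            out.extend(blk.params())
        return out

    def _buffers(self):
        for b, blk in enumerate(self.blocks):
            for l, layer in enumerate(blk.layers):
                if isinstance(layer, BatchNorm2d):
                    yield f"blk{b}.l{l}", layer

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        for key, bn in self._buffers():
            state[f"{key}.running_mean"] = bn.running_mean
            state[f"{key}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value = np.asarray(state[p.name]).astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)
        for key, bn in self._buffers():
            bn.running_mean = np.asarray(state[f"{key}.running_mean"])
            bn.running_var = np.asarray(state[f"{key}.running_var"])


class UNetGenerator(_Model):
    """Encoder-decoder with skip concatenations; maps (B,1,H,W) -> (B,1,H,W)."""

    def __init__(self, spec: GeneratorSpec, seed: int | None = None,
                 dtype=np.float32):
        self.spec = spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        enc = spec.encoder_channels
        d = spec.depth
        k, s = spec.kernel, spec.stride

        self.enc_blocks: list[_Block] = []
        c_prev = 1
        for i, c in enumerate(enc):
            layers: list[Layer] = [Conv2d(c_prev, c, k, s, 1, rng, dtype,
                                          name=f"enc{i}")]
            if spec.batch_norm and 0 < i < d - 1:
                layers.append(BatchNorm2d(c, dtype=dtype, name=f"enc{i}.bn"))
            layers.append(LeakyReLU(spec.leaky_slope))
            self.enc_blocks.append(_Block(layers))
            c_prev = c

        self.dec_blocks: list[_Block] = []
        for j in range(d):
            c_in = enc[d - 1] if j == 0 else enc[d - j] + enc[d - 1 - j]
            c_out = enc[d - 1 - j]
            layers = [ConvTranspose2d(c_in, c_out, k, s, 1, rng, dtype,
                                      name=f"dec{j}")]
            if spec.batch_norm:
                layers.append(BatchNorm2d(c_out, dtype=dtype, name=f"dec{j}.bn"))
            layers.append(ReLU())
            if spec.noise_mode == "dropout" and j < 3:
                layers.append(Dropout(spec.dropout_p,
                                      np.random.default_rng(rng.integers(2**31))))
            self.dec_blocks.append(_Block(layers))

        self.head = _Block([
            Conv2d(enc[0], 1, kernel=1, stride=1, padding=0, rng=rng,
                   dtype=dtype, name="head"),
            Sigmoid(),
        ])
        self.blocks = self.enc_blocks + self.dec_blocks + [self.head]
        self._skip_channels = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Map a (B, H, W, 1) batch of sinograms to estimates of equal shape."""
        spec = self.spec
        h, w = x.shape[1], x.shape[2]
        if h % (1 << spec.depth) or w % (1 << spec.depth):
            raise ValueError(f"input {x.shape} not divisible by 2^depth")
        skips = []
        out = x
        for blk in self.enc_blocks:
            out = blk.forward(out, train)
            skips.append(out)
        self._skip_channels = [s.shape[-1] for s in skips]
        d = spec.depth
        for j, blk in enumerate(self.dec_blocks):
            if j > 0:
                out = np.concatenate([out, skips[d - 1 - j]], axis=-1)
            out = blk.forward(out, train)
        return self.head.forward(out, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        grad = self.head.backward(dy)
        enc_grads: list[np.ndarray | None] = [None] * d
        for j in range(d - 1, -1, -1):
            grad = self.dec_blocks[j].backward(grad)
            if j > 0:
                # concat was [prev_out, skip]; split channels accordingly
                c_split = grad.shape[-1] - self._skip_channels[d - 1 - j]
                enc_grads[d - 1 - j] = grad[..., c_split:]
                grad = np.ascontiguousarray(grad[..., :c_split])
        # grad now flows into the deepest encoder output
        acc = grad
        for i in range(d - 1, -1, -1):
            if enc_grads[i] is not None:
                acc = acc + enc_grads[i]
            acc = self.enc_blocks[i].backward(np.ascontiguousarray(acc))
        return acc


class PatchDiscriminator(_Model):
    """Fully convolutional conditioned discriminator emitting a patch map."""

    def __init__(self, spec: DiscriminatorSpec, seed: int | None = None,
                 dtype=np.float32):
        self.spec = spec
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        n = len(spec.channels)
        self.blocks = []
        c_prev = spec.in_channels
        for i, (c, s) in enumerate(zip(spec.channels, spec.strides)):
            layers: list[Layer] = [Conv2d(c_prev, c, spec.kernel, s, 1, rng,
                                          dtype, name=f"d{i}")]
            if spec.batch_norm and 0 < i < n - 1:
                layers.append(BatchNorm2d(c, dtype=dtype, name=f"d{i}.bn"))
            layers.append(Sigmoid() if i == n - 1 else ReLU())
            self.blocks.append(_Block(layers))
            c_prev = c

    def forward(self, x_pair: np.ndarray, train: bool = True) -> np.ndarray:
        if x_pair.shape[-1] != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} input channels "
                f"(conditioning + candidate), got {x_pair.shape[-1]}")
        out = x_pair
        for blk in self.blocks:
            out = blk.forward(out, train)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for blk in reversed(self.blocks):
            dy = blk.backward(dy)
        return dy


def build_generator(spec: GeneratorSpec, seed: int | None = None,
                    dtype=np.float32) -> UNetGenerator:
    return UNetGenerator(spec, seed=seed, dtype=dtype)


def build_discriminator(spec: DiscriminatorSpec, seed: int | None = None,
                        dtype=np.float32) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed=seed, dtype=dtype)


def discriminator_decision(patch_map: np.ndarray) -> float:
    """The discriminator's verdict: arithmetic mean of all patch probabilities."""
    patch_map = np.asarray(patch_map)
    if patch_map.size == 0:
        raise ValueError("empty patch map")
    return float(patch_map.mean())


def count_parameters(model: _Model) -> ModelParams:
    """Exact count of trainable scalars, per parameter tensor and total."""
    ledger = [(p.name, tuple(p.value.shape), p.size) for p in model.params()]
    return ModelParams(ledger)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, generator: UNetGenerator, seed: int = 0,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint: architecture spec + weights + seed."""
    meta = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in generator.spec.__dict__.items()},
        "seed": seed,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **generator.state_dict())


def load_checkpoint(path) -> tuple[UNetGenerator, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    spec_kw = meta["spec"]
    spec_kw["input_size"] = tuple(spec_kw["input_size"])
    gen = UNetGenerator(GeneratorSpec(**spec_kw))
    gen.load_state_dict(state)
    return gen, meta
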