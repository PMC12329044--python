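"""Decoder: hidden grid h_T -> voxel occupancy probabilities.

The final LSTM hidden grid (N x N x N, N_h channels) is upsampled to the
output resolution N_v by interleaving nearest-neighbour unpooling with
zero-padded 3-D convolutions and LeakyReLU nonlinearities, ending in a
2-channel convolution and a voxel-wise softmax over (background, occupied).

Two variants share the same skeleton:

* ``basic`` — five convolutions (four scheduled blocks plus the final
  2-channel conv).
* ``residual`` — the four blocks gain identity skip connections (a 1x1x1
  convolution on the skip path when the channel count changes), followed by
  the final convolution.

Unpooling is placed on the first ``log2(N_v / N)`` blocks, so the default
4 -> 32 configuration doubles resolution in the first three blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Parameter, Tensor, conv3d, he_uniform, leaky_relu, unpool3d

__all__ = ["DecoderConfig", "OccupancyPrediction", "Decoder", "voxel_softmax", "softmax2"]


@dataclass
class DecoderConfig:
    variant: str = "basic"
    channels: tuple[int, ...] = (128, 64, 32, 16, 8)  # channels[0] = N_h input
    unpool_factor: int = 2
    grid_n: int = 4
    resolution: int = 32
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("basic", "residual"):
            raise ValueError("variant must be 'basic' or 'residual'")
        if len(self.channels) != 5:
            raise ValueError("channel schedule must list 5 values (input + 4 blocks)")
        ratio = self.resolution / self.grid_n
        n_up = round(np.log(ratio) / np.log(self.unpool_factor)) if ratio > 1 else 0
        if self.grid_n * self.unpool_factor**n_up != self.resolution or n_up > 4:
            raise ValueError(
                f"resolution {self.resolution} is not reachable from grid {self.grid_n} "
                f"with <= 4 unpool stages of factor {self.unpool_factor}"
            )
        self.n_unpool: int = n_up


@dataclass
class OccupancyPrediction:
    """Per-voxel (background, occupied) probabilities, summing to 1."""

    probs: np.ndarray  # (N_v, N_v, N_v, 2)
    tensor: Tensor | None = field(default=None, repr=False)

    @property
    def occupied(self) -> np.ndarray:
        return self.probs[..., 1]

    @property
    def resolution(self) -> int:
        return self.probs.shape[0]


def voxel_softmax(logits: np.ndarray) -> np.ndarray:
    """Per-voxel 2-class softmax on the last axis, stabilized by max-shift."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape[-1] != 2:
        raise ValueError("expected 2 channels on the last axis")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax2(logits: Tensor) -> Tensor:
    """Differentiable 2-class softmax over axis 1 of (B, 2, D, H, W)."""
    shift = Tensor(logits.data.max(axis=1, keepdims=True))  # constant: grads cancel
    e = (logits - shift).exp()
    return e / e.sum(axis=1, keepdims=True)


class Decoder:
    def __init__(self, config: DecoderConfig | None = None):
        self.config = config or DecoderConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Parameter] = {}
        chans = list(cfg.channels)
        for i in range(4):
            ci, co = chans[i], chans[i + 1]
            self.params[f"conv{i}.w"] = Parameter(
                he_uniform(rng, (co, ci, 3, 3, 3), fan_in=ci * 27)
            )
            self.params[f"conv{i}.b"] = Parameter(np.zeros(co))
            if cfg.variant == "residual" and ci != co:
                self.params[f"skip{i}.w"] = Parameter(
                    he_uniform(rng, (co, ci, 1, 1, 1), fan_in=ci)
                )
        self.params["final.w"] = Parameter(
            he_uniform(rng, (2, chans[4], 3, 3, 3), fan_in=chans[4] * 27)
        )
        self.params["final.b"] = Parameter(np.zeros(2))

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def forward(self, h: Tensor) -> Tensor:
        """(B, N_h, N, N, N) hidden grid -> (B, 2, N_v, N_v, N_v) logits."""
        cfg = self.config
        if h.shape[1] != cfg.channels[0] or h.shape[-1] != cfg.grid_n:
            raise ValueError(
                f"hidden grid shape {h.shape} does not match decoder config "
                f"(channels[0]={cfg.channels[0]}, grid_n={cfg.grid_n})"
            )
        x = h
        for i in range(4):
            if i < cfg.n_unpool:
                x = unpool3d(x, cfg.unpool_factor)
            y = conv3d(x, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"])
            y = leaky_relu(y, cfg.leaky_slope)
            if cfg.variant == "residual":
                skip = x
                if f"skip{i}.w" in self.params:
                    skip = conv3d(x, self.params[f"skip{i}.w"], None, pad=0)
                y = y + skip
            x = y
        return conv3d(x, self.params["final.w"], self.params["final.b"])

    def decode(self, state_or_h) -> OccupancyPrediction:
        """Full decode of a :class:`GridState` (or raw hidden tensor).

        Returns voxel probabilities shaped (N_v, N_v, N_v, 2) for a
        single-sample batch, channel 0 background / channel 1 occupied.
        """
        h = getattr(state_or_h, "h", state_or_h)
        if not isinstance(h, Tensor):
            h = Tensor(h)
        logits = self.forward(h)
        probs = softmax2(logits)
        grid = np.ascontiguousarray(probs.data[0].transpose(1, 2, 3, 0))
        return OccupancyPrediction(probs=grid, tensor=probs)

    # -- serialization -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.params.items()}

    def restore(self, arrays: dict[str, np.ndarray]) -> None:
        for name, arr in arrays.items():
            if name not in self.params:
                raise KeyError(f"unexpected decoder parameter {name!r}")
            self.params[name].data = np.array(arr, dtype=np.float64)
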