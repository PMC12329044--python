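"""View encoder: RGB image -> fixed-size latent vector.

A convolutional backbone truncated before any classification head produces a
spatial feature map; the map is flattened and passed through a fully
connected layer sized lazily on the first forward pass, followed by
LeakyReLU (negative slope 0.1 by default).  Two backbones are available:

* ``compact`` — four stride-2 conv blocks (channels 16 -> 32 -> 64 -> 128),
  small enough to train on a CPU in seconds; the default for tests.
* ``b0_style`` — a mobile-inverted-bottleneck stage schedule mirroring
  EfficientNet-B0's stage widths, strides and kernel sizes (no
  squeeze-excitation).  Weights are randomly initialized; externally trained
  weights with matching names/shapes can be loaded via
  :meth:`Encoder.load_backbone_weights`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, conv2d, depthwise_conv2d, he_uniform, leaky_relu

__all__ = ["EncoderConfig", "Encoder", "LatentShapeError"]

# EfficientNet-B0 stage schedule: (expand_ratio, out_channels, repeats, stride, kernel)
_B0_STAGES = (
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
)


class LatentShapeError(ValueError):
    """Input size changed after the lazy fully connected layer was sized."""


@dataclass
class EncoderConfig:
    backbone: str = "compact"
    latent_dim: int = 1024
    leaky_slope: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in ("compact", "b0_style"):
            raise ValueError("backbone must be 'compact' or 'b0_style'")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")


class Encoder:
    def __init__(self, config: EncoderConfig | None = None):
        self.config = config or EncoderConfig()
        self.params: dict[str, Parameter] = {}
        self._flat_dim: int | None = None
        self._rng = np.random.default_rng(self.config.seed)
        if self.config.backbone == "compact":
            self._build_compact()
        else:
            self._build_b0_style()

    # -- parameter plumbing --------------------------------------------------
    def _add(self, name: str, shape: tuple[int, ...], fan_in: int) -> Parameter:
        p = Parameter(he_uniform(self._rng, shape, fan_in))
        self.params[name] = p
        return p

    def _add_zero(self, name: str, shape: tuple[int, ...]) -> Parameter:
        p = Parameter(np.zeros(shape))
        self.params[name] = p
        return p

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def load_backbone_weights(self, path) -> int:
        """Load externally trained backbone weights from an ``.npz`` archive.

        Arrays are assigned by parameter name; every provided name must exist
        with a matching shape.  Returns the number of tensors loaded.
        """
        archive = np.load(path)
        loaded = 0
        for name in archive.files:
            if name not in self.params:
                raise KeyError(f"unknown backbone parameter {name!r}")
            if archive[name].shape != self.params[name].data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: "
                    f"{archive[name].shape} vs {self.params[name].data.shape}"
                )
            self.params[name].data = archive[name].astype(np.float64)
            loaded += 1
        return loaded

    # -- backbone construction -------------------------------------------------
    def _build_compact(self):
        channels = [3, 16, 32, 64, 128]
        for i, (ci, co) in enumerate(zip(channels[:-1], channels[1:])):
            self._add(f"conv{i}.w", (co, ci, 3, 3), fan_in=ci * 9)
            self._add_zero(f"conv{i}.b", (co,))

    def _build_b0_style(self):
        self._add("stem.w", (32, 3, 3, 3), fan_in=27)
        self._add_zero("stem.b", (32,))
        c_in = 32
        for si, (expand, c_out, repeats, stride, k) in enumerate(_B0_STAGES):
            for r in range(repeats):
                prefix = f"stage{si}.block{r}"
                s = stride if r == 0 else 1
                mid = c_in * expand
                if expand != 1:
                    self._add(f"{prefix}.expand.w", (mid, c_in, 1, 1), fan_in=c_in)
                    self._add_zero(f"{prefix}.expand.b", (mid,))
                self._add(f"{prefix}.dw.w", (mid, k, k), fan_in=k * k)
                self._add_zero(f"{prefix}.dw.b", (mid,))
                self._add(f"{prefix}.project.w", (c_out, mid, 1, 1), fan_in=mid)
                self._add_zero(f"{prefix}.project.b", (c_out,))
                c_in = c_out

    # -- forward -----------------------------------------------------------------
    @staticmethod
    def _to_batch(images) -> Tensor:
        """Accept (H,W,3), (B,H,W,3) or a list of (H,W,3); -> Tensor (B,3,H,W)."""
        if isinstance(images, Tensor):
            return images
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected (B, H, W, 3) RGB images, got {arr.shape}")
        return Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))

    def backbone_features(self, images) -> Tensor:
        """Spatial feature map (B, C, h', w') from the truncated backbone."""
        x = self._to_batch(images)
        slope = self.config.leaky_slope
        if self.config.backbone == "compact":
            for i in range(4):
                x = conv2d(x, self.params[f"conv{i}.w"], self.params[f"conv{i}.b"],
                           stride=2, pad=1)
                x = leaky_relu(x, slope)
            return x
        x = conv2d(x, self.params["stem.w"], self.params["stem.b"], stride=2, pad=1)
        x = leaky_relu(x, slope)
        c_in = 32
        for si, (expand, c_out, repeats, stride, k) in enumerate(_B0_STAGES):
            for r in range(repeats):
                prefix = f"stage{si}.block{r}"
                s = stride if r == 0 else 1
                residual = x
                h = x
                if expand != 1:
                    h = leaky_relu(
                        conv2d(h, self.params[f"{prefix}.expand.w"],
                               self.params[f"{prefix}.expand.b"]), slope)
                h = leaky_relu(
                    depthwise_conv2d(h, self.params[f"{prefix}.dw.w"],
                                     self.params[f"{prefix}.dw.b"],
                                     stride=s, pad=k // 2), slope)
                h = conv2d(h, self.params[f"{prefix}.project.w"],
                           self.params[f"{prefix}.project.b"])
                if s == 1 and c_in == c_out:
                    h = h + residual
                x = h
                c_in = c_out
        return x

    def _ensure_fc(self, flat_dim: int) -> None:
        if self._flat_dim is None:
            self._flat_dim = flat_dim
            rng = np.random.default_rng(self.config.seed + 1)
            self.params["fc.w"] = Parameter(
                he_uniform(rng, (flat_dim, self.config.latent_dim), fan_in=flat_dim)
            )
            self.params["fc.b"] = Parameter(np.zeros(self.config.latent_dim))
        elif flat_dim != self._flat_dim:
            raise LatentShapeError(
                f"flattened feature size {flat_dim} does not match the size "
                f"{self._flat_dim} fixed on the first forward pass"
            )

    def encode(self, images) -> Tensor:
        """(B, latent_dim) latents: backbone -> flatten -> FC -> LeakyReLU."""
        feat = self.backbone_features(images)
        b = feat.shape[0]
        flat_dim = int(np.prod(feat.shape[1:]))
        self._ensure_fc(flat_dim)
        flat = feat.reshape(b, flat_dim)
        z = flat @ self.params["fc.w"] + self.params["fc.b"].reshape(1, -1)
        return leaky_relu(z, self.config.leaky_slope)

    # -- serialization ---------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.params.items()}

    @property
    def flat_dim(self) -> int | None:
        return self._flat_dim

    def restore(self, arrays: dict[str, np.ndarray], flat_dim: int | None) -> None:
        if flat_dim is not None:
            self._flat_dim = None
            self._ensure_fc(flat_dim)
        for name, arr in arrays.items():
            if name not in self.params:
                raise KeyError(f"unexpected encoder parameter {name!r}")
            self.params[name].data = np.array(arr, dtype=np.float64)
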