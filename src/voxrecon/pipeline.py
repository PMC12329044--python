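"""End-to-end reconstruction: encode views, fuse with the 3-D LSTM, decode.

The three components are trained jointly with a voxel-wise 2-class
cross-entropy against binary ground-truth occupancy grids, using Adam with
global-norm gradient clipping (the un-gated h = tanh(s) recurrence can
otherwise produce large state gradients early in training).  Training is
deterministic for a fixed seed and thread count.

Checkpoints are ``.npz`` archives of all named parameter tensors plus a JSON
snapshot of the three configs and the lazily resolved encoder flatten size,
so a reloaded model reconstructs bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .decoder import Decoder, DecoderConfig, OccupancyPrediction, softmax2
from .encoder import Encoder, EncoderConfig
from .metrics import voxel_iou
from .recurrence import ConvLSTM3D, GridState, LSTMConfig
from .voxel_io import VoxelGrid

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "ReconstructionModel",
    "voxel_cross_entropy",
    "train",
    "reconstruct",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    views_per_sample: int | None = None  # None = use every available view
    random_view_range: tuple[int, int] | None = None  # (T_min, T_max) per step
    threshold: float = 0.5
    clip_norm: float = 10.0
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    iou: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)


def voxel_cross_entropy(pred, truth) -> Tensor:
    """Mean voxel-wise binary cross-entropy.

    ``pred`` is an :class:`OccupancyPrediction` or a (B, 2, D, H, W) probability
    tensor; ``truth`` a binary :class:`VoxelGrid` or array.  The occupied-class
    probability is clipped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    if isinstance(pred, OccupancyPrediction):
        probs = pred.tensor
        if probs is None:
            probs = Tensor(pred.probs.transpose(3, 0, 1, 2)[None])
    else:
        probs = pred if isinstance(pred, Tensor) else Tensor(pred)
    y = truth.occupancy if isinstance(truth, VoxelGrid) else np.asarray(truth, dtype=np.float64)
    if probs.shape[2:] != y.shape:
        raise ValueError(f"resolution mismatch: pred {probs.shape[2:]} vs truth {y.shape}")
    p_occ = probs[:, 1].clip(1e-7, 1.0 - 1e-7)
    yb = y[None]
    ll = Tensor(yb) * p_occ.log() + Tensor(1.0 - yb) * (1.0 - p_occ).log()
    return -ll.mean()


class ReconstructionModel:
    """Encoder + 3-D convolutional LSTM + decoder, jointly trainable."""

    def __init__(
        self,
        encoder_config: EncoderConfig | None = None,
        lstm_config: LSTMConfig | None = None,
        decoder_config: DecoderConfig | None = None,
    ):
        self.encoder = Encoder(encoder_config)
        self.lstm = ConvLSTM3D(lstm_config)
        self.decoder = Decoder(decoder_config)
        ec, lc, dc = self.encoder.config, self.lstm.config, self.decoder.config
        if ec.latent_dim != lc.latent_dim:
            raise ValueError("encoder latent_dim must match LSTM latent_dim")
        if dc.channels[0] != lc.hidden or dc.grid_n != lc.grid_n:
            raise ValueError("decoder input channels/grid must match the LSTM grid")

    def parameters(self):
        return (
            self.encoder.parameters()
            + self.lstm.parameters()
            + self.decoder.parameters()
        )

    def forward(self, views: np.ndarray) -> Tensor:
        """(T, H, W, 3) ordered views -> (1, 2, N_v, N_v, N_v) probabilities."""
        views = np.asarray(views, dtype=np.float64)
        if views.ndim == 3:
            views = views[None]
        latents = self.encoder.encode(views)  # (T, latent)
        state: GridState = self.lstm.zero_state(batch=1)
        for t in range(latents.shape[0]):
            state = self.lstm.step(latents[t : t + 1], state)
        logits = self.decoder.forward(state.h)
        return softmax2(logits)

    def predict(self, views: np.ndarray) -> OccupancyPrediction:
        probs = self.forward(views)
        grid = np.ascontiguousarray(probs.data[0].transpose(1, 2, 3, 0))
        return OccupancyPrediction(probs=grid, tensor=probs)

    # -- checkpointing -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for prefix, comp in (("encoder", self.encoder), ("lstm", self.lstm),
                             ("decoder", self.decoder)):
            for name, arr in comp.state_arrays().items():
                arrays[f"{prefix}/{name}"] = arr
        meta = {
            "encoder": asdict(self.encoder.config),
            "lstm": asdict(self.lstm.config),
            "decoder": {k: v for k, v in asdict(self.decoder.config).items()
                        if k != "n_unpool"},
            "flat_dim": self.encoder.flat_dim,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "ReconstructionModel":
        archive = np.load(path)
        meta = json.loads(bytes(archive["__meta__"]).decode())
        enc_cfg = EncoderConfig(**meta["encoder"])
        lstm_cfg = LSTMConfig(**meta["lstm"])
        dec_meta = dict(meta["decoder"])
        dec_meta["channels"] = tuple(dec_meta["channels"])
        dec_cfg = DecoderConfig(**dec_meta)
        model = cls(enc_cfg, lstm_cfg, dec_cfg)
        groups: dict[str, dict[str, np.ndarray]] = {"encoder": {}, "lstm": {}, "decoder": {}}
        for key in archive.files:
            if key == "__meta__":
                continue
            prefix, name = key.split("/", 1)
            groups[prefix][name] = archive[key]
        model.encoder.restore(groups["encoder"], meta["flat_dim"])
        model.lstm.restore(groups["lstm"])
        model.decoder.restore(groups["decoder"])
        return model


def _select_views(views: np.ndarray, config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    if config.random_view_range is not None:
        lo, hi = config.random_view_range
        t = int(rng.integers(lo, hi + 1))
        idx = np.sort(rng.choice(len(views), size=min(t, len(views)), replace=False))
        return views[idx]
    if config.views_per_sample is not None:
        return views[: config.views_per_sample]
    return views


def train(samples, model: ReconstructionModel, config: TrainConfig) -> TrainHistory:
    """Jointly train all components on (views, ground_truth) samples.

    ``samples`` is a sequence of either :class:`~voxrecon.voxel_io.MultiViewSample`
    objects with ground truth or ``(views_array, occupancy_array)`` pairs.
    One Adam step is taken per sample per epoch, in a fixed order, so the loss
    history is reproducible for a given seed.
    """
    pairs = []
    for s in samples:
        if hasattr(s, "views"):
            if s.ground_truth is None:
                raise ValueError(f"sample {s.object_id} has no ground truth")
            pairs.append((np.stack(s.views), s.ground_truth.occupancy))
        else:
            views, occ = s
            pairs.append((np.asarray(views, dtype=np.float64),
                          np.asarray(occ, dtype=np.float64)))
    if not pairs:
        raise ValueError("no training samples")

    rng = np.random.default_rng(config.seed)
    # materialize the lazy FC before collecting parameters
    model.encoder.encode(pairs[0][0][:1])
    opt = Adam(model.parameters(), lr=config.learning_rate, clip_norm=config.clip_norm)
    history = TrainHistory(seed=config.seed, config=asdict(config))

    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    for epoch in range(config.epochs):
        losses, ious = [], []
        for views, occ in pairs:
            use = _select_views(views, config, rng)
            probs = model.forward(use)
            loss = voxel_cross_entropy(probs, occ)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; last sample had "
                    f"{len(use)} views, occupancy mean {occ.mean():.4f}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            ious.append(voxel_iou(probs.data[0, 1], occ, config.threshold))
        history.loss.append(float(np.mean(losses)))
        history.iou.append(float(np.mean(ious)))
        if ckpt_dir:
            model.save(ckpt_dir / f"epoch_{epoch:04d}.npz")
        logger.debug("epoch %d: loss %.5f iou %.4f", epoch,
                     history.loss[-1], history.iou[-1])
    return history


def reconstruct(views, model: ReconstructionModel, threshold: float = 0.5):
    """Reconstruct a binary voxel grid from ordered views.

    Returns ``(grid, prob_grid)``: the binarized :class:`VoxelGrid` (occupied
    iff p > threshold, strictly) and the raw occupied-probability array.
    """
    views = np.stack(views) if isinstance(views, (list, tuple)) else np.asarray(views)
    pred = model.predict(views)
    prob = pred.occupied
    grid = VoxelGrid((prob > threshold).astype(np.float64), is_binary=True)
    return grid, prob
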