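"""3-D convolutional LSTM grid that fuses a sequence of view latents.

An N x N x N grid of LSTM units shares one set of gate parameters.  Each unit
(i, j, k) holds a hidden state h(i,j,k) of N_h channels.  For a view latent
x_t the update is

    f_t = sigmoid(W_f x_t + U_f * h_{t-1} + b_f)          (forget gate)
    i_t = sigmoid(W_i x_t + U_i * h_{t-1} + b_i)          (input gate)
    s_t = f_t (.) s_{t-1} + i_t (.) tanh(W_s x_t + U_s * h_{t-1} + b_s)
    h_t = tanh(s_t)

where W_* are per-gate linear maps from the latent onto the grid (one
N_h-vector per unit), ``*`` is a same-size zero-padded 3-D convolution over
the hidden grid, and (.) is elementwise.  There is deliberately NO output
gate: h is tanh of the cell state directly, which keeps every hidden value
inside (-1, 1) and bounds |s_t| <= |s_{t-1}| + 1 at every step.

The latent transform T(x) is the identity — the per-gate W is the only
learned input map.  State is initialized to zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor, conv3d, he_uniform, sigmoid, tanh

__all__ = ["LSTMConfig", "GridState", "ConvLSTM3D", "input_transform"]


@dataclass
class LSTMConfig:
    grid_n: int = 4
    hidden: int = 128
    kernel: int = 3
    latent_dim: int = 1024
    seed: int = 0

    def __post_init__(self):
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if min(self.grid_n, self.hidden, self.latent_dim) < 1:
            raise ValueError("grid_n, hidden and latent_dim must be positive")


@dataclass
class GridState:
    """Hidden and cell tensors, internally (B, N_h, N, N, N)."""

    h: Tensor
    s: Tensor

    @property
    def grid_n(self) -> int:
        return self.h.shape[-1]

    @property
    def hidden(self) -> int:
        return self.h.shape[1]

    def h_grid(self) -> np.ndarray:
        """Hidden state as (N, N, N, N_h) for a single-sample batch."""
        return np.ascontiguousarray(self.h.data[0].transpose(1, 2, 3, 0))

    def s_grid(self) -> np.ndarray:
        return np.ascontiguousarray(self.s.data[0].transpose(1, 2, 3, 0))


def input_transform(x: Tensor, W: Tensor, grid_n: int, hidden: int) -> Tensor:
    """Map a batch of latents onto the grid: (B, latent) -> (B, N_h, N, N, N).

    The latent itself is the transformed input (T = identity); W supplies one
    N_h-vector per grid unit.
    """
    if x.shape[-1] != W.shape[0]:
        raise ValueError(
            f"latent dim {x.shape[-1]} does not match W input dim {W.shape[0]}"
        )
    b = x.shape[0]
    g = x @ W  # (B, N^3 * N_h)
    g = g.reshape(b, grid_n, grid_n, grid_n, hidden)
    return g.transpose(0, 4, 1, 2, 3)


class ConvLSTM3D:
    """The shared-parameter 3-D convolutional LSTM grid."""

    GATES = ("f", "i", "s")

    def __init__(self, config: LSTMConfig | None = None):
        self.config = config or LSTMConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n3h = cfg.grid_n**3 * cfg.hidden
        k = cfg.kernel
        self.params: dict[str, Parameter] = {}
        for gate in self.GATES:
            self.params[f"W_{gate}"] = Parameter(
                he_uniform(rng, (cfg.latent_dim, n3h), fan_in=cfg.latent_dim)
            )
            self.params[f"U_{gate}"] = Parameter(
                he_uniform(rng, (cfg.hidden, cfg.hidden, k, k, k),
                           fan_in=cfg.hidden * k**3)
            )
            self.params[f"b_{gate}"] = Parameter(np.zeros(cfg.hidden))

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def zero_state(self, batch: int = 1) -> GridState:
        cfg = self.config
        shape = (batch, cfg.hidden, cfg.grid_n, cfg.grid_n, cfg.grid_n)
        return GridState(Tensor(np.zeros(shape)), Tensor(np.zeros(shape)))

    def _gate_preact(self, gate: str, x: Tensor, h: Tensor) -> Tensor:
        cfg = self.config
        wx = input_transform(x, self.params[f"W_{gate}"], cfg.grid_n, cfg.hidden)
        uh = conv3d(h, self.params[f"U_{gate}"], None)
        b = self.params[f"b_{gate}"].reshape(1, -1, 1, 1, 1)
        return wx + uh + b

    def step(self, x: Tensor, state: GridState) -> GridState:
        """One LSTM update for a batch of latents x: (B, latent_dim)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        preacts = {}
        for gate, label in (("f", "forget"), ("i", "input"), ("s", "state")):
            pre = self._gate_preact(gate, x, state.h)
            if not np.all(np.isfinite(pre.data)):
                raise FloatingPointError(f"non-finite values in the {label} gate")
            preacts[gate] = pre
        f = sigmoid(preacts["f"])
        i = sigmoid(preacts["i"])
        g = tanh(preacts["s"])
        s_new = f * state.s + i * g
        h_new = tanh(s_new)
        if not np.all(np.isfinite(s_new.data)):
            raise FloatingPointError("non-finite values in the cell state")
        return GridState(h_new, s_new)

    def run_sequence(self, latents, state: GridState | None = None) -> GridState:
        """Apply :meth:`step` over an ordered latent sequence from zero state.

        ``latents`` is a list of (B, latent) tensors/arrays or a single
        (T, B, latent) / (T, latent) array.
        """
        if isinstance(latents, np.ndarray):
            if latents.ndim == 2:
                latents = [latents[t : t + 1] for t in range(latents.shape[0])]
            else:
                latents = [latents[t] for t in range(latents.shape[0])]
        latents = list(latents)
        if len(latents) == 0:
            raise ValueError("run_sequence needs at least one latent")
        if state is None:
            first = latents[0]
            b = first.shape[0] if getattr(first, "ndim", 1) > 1 else 1
            state = self.zero_state(b)
        for x in latents:
            state = self.step(x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x)), state)
        return state

    # -- serialization -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data for name, p in self.params.items()}

    def restore(self, arrays: dict[str, np.ndarray]) -> None:
        for name, arr in arrays.items():
            if name not in self.params:
                raise KeyError(f"unexpected LSTM parameter {name!r}")
            self.params[name].data = np.array(arr, dtype=np.float64)
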