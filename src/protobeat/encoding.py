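"""Sequence framing, LSTM recurrence, and attention pooling.

A raw beat of length L is split into T equal-width frames (width n = floor(L/T),
remainder samples dropped) which form the step inputs of a stacked, optionally
bidirectional LSTM; per-step hidden states are pooled into a fixed-length
embedding by softmax attention. These functions are the single-sequence,
inspectable counterparts of the batched engine in ``_network``; both share the
same cell arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _network
from .data import LabeledSequence


@dataclass
class LSTMCellParams:
    """Weights of a single LSTM cell.

    ``Wx`` (4H, n) and ``Wh`` (4H, H) stack the four gate blocks in the order
    [input gate, forget gate, cell candidate, output gate]; ``b`` is (4H,).
    """

    Wx: np.ndarray
    Wh: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.Wx = np.atleast_2d(np.asarray(self.Wx, dtype=np.float64))
        self.Wh = np.atleast_2d(np.asarray(self.Wh, dtype=np.float64))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        fourH = self.Wx.shape[0]
        if fourH % 4 != 0 or self.Wh.shape != (fourH, fourH // 4) or self.b.shape != (fourH,):
            raise ValueError(
                f"inconsistent cell shapes: Wx {self.Wx.shape}, Wh {self.Wh.shape}, b {self.b.shape}"
            )

    @property
    def hidden_size(self) -> int:
        return self.Wx.shape[0] // 4

    @classmethod
    def scalar(cls, w: float = 1.0, bias: float = 0.0) -> "LSTMCellParams":
        """A 1-unit cell with every weight equal to ``w`` — handy for hand checks."""
        return cls(np.full((4, 1), w), np.full((4, 1), w), np.full(4, bias))


def segment_series(series: LabeledSequence | np.ndarray, T: int) -> np.ndarray:
    """Split a raw signal into ``T`` equal-length contiguous frames.

    Returns an array of shape (T, n) with n = floor(L/T); the trailing L - T*n
    samples are dropped so all frames have equal width.
    """
    values = series.values if isinstance(series, LabeledSequence) else np.asarray(series, float)
    L = values.size
    if T < 1:
        raise ValueError(f"step count T must be >= 1, got {T}")
    if T > L:
        raise ValueError(f"cannot split a series of length {L} into T={T} frames")
    n = L // T
    return values[: T * n].reshape(T, n).copy()


def segment_batch(X: np.ndarray, T: int) -> np.ndarray:
    """Frame every row of an (N, L) matrix; returns (N, T, n)."""
    X = np.asarray(X, dtype=np.float64)
    L = X.shape[1]
    if T > L:
        raise ValueError(f"cannot split series of length {L} into T={T} frames")
    n = L // T
    return X[:, : T * n].reshape(X.shape[0], T, n).copy()


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, cell: LSTMCellParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update.

    Gates are sigmoids of affine maps of (x_t, h_prev); the cell state blends
    the previous state (forget gate) with a tanh candidate (input gate), and
    the hidden state is the output gate times tanh of the cell state, so every
    hidden component lies strictly inside (-1, 1).
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=np.float64))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=np.float64))
    H = cell.hidden_size
    if x_t.shape[0] != cell.Wx.shape[1] or h_prev.shape[0] != H or c_prev.shape[0] != H:
        raise ValueError(
            f"shape mismatch: x {x_t.shape}, h {h_prev.shape}, c {c_prev.shape} "
            f"vs cell (n={cell.Wx.shape[1]}, H={H})"
        )
    a = cell.Wx @ x_t + cell.Wh @ h_prev + cell.b
    ig = _network.sigmoid(a[:H])
    fg = _network.sigmoid(a[H : 2 * H])
    g = np.tanh(a[2 * H : 3 * H])
    og = _network.sigmoid(a[3 * H :])
    c_t = fg * c_prev + ig * g
    h_t = og * np.tanh(c_t)
    return h_t, c_t


def encode(
    frames: np.ndarray, params: dict[str, np.ndarray], n_layers: int, bidirectional: bool
) -> np.ndarray:
    """Run the stacked (bi)directional encoder on one framed series.

    frames: (T, n). Returns per-step hidden states H of shape (T, u), where
    u = 2 * hidden size when bidirectional (forward block first, then backward).
    """
    frames = np.asarray(frames, dtype=np.float64)
    H, _ = _network.encoder_forward(params, frames[None], n_layers, bidirectional)
    return H[0]


def attend(
    H: np.ndarray,
    W_alpha: np.ndarray,
    b_alpha: np.ndarray,
    V_alpha: np.ndarray,
    use_tanh: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Attention-pool per-step states into one embedding.

    Scores are V^T (W^T h_t + b) per step (optionally tanh-squashed before the
    inner product); the softmax over steps gives convex weights alpha, and the
    embedding is e = sum_t alpha_t h_t. Returns (alpha, e).
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("H must be a non-empty (T, u) matrix")
    alpha, e, _ = _network.attention_forward(
        H[None], np.asarray(W_alpha, float), np.asarray(b_alpha, float),
        np.asarray(V_alpha, float), use_tanh
    )
    return alpha[0], e[0]
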