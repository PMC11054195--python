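"""Numerical engine: batched forward/backward passes for the recurrent prototype network.

All parameters live in a flat ``dict[str, ndarray]`` (float64). Layout:

- ``enc{l}{d}_Wx`` : (4H, D_in)  input weights of LSTM layer ``l``, direction ``d`` in ``{f, b}``
- ``enc{l}{d}_Wh`` : (4H, H)     recurrent weights
- ``enc{l}{d}_b``  : (4H,)       gate biases
- ``att_W`` (u, D), ``att_b`` (D,), ``att_V`` (D,) : additive attention
- ``proto`` (K, u) : prototype vectors
- ``head``  (C, K) : linear classifier over prototype similarities

Gate order within the leading 4H axis is [input, forget, cell-candidate, output].
Everything here is deterministic given its inputs; randomness (init, dropout)
is injected by the caller through numpy Generators.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = x - np.max(x, axis=axis, keepdims=True)
    ex = np.exp(shifted)
    return ex / ex.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# parameter initialisation


def init_params(
    n_frame: int,
    hidden_size: int,
    n_layers: int,
    bidirectional: bool,
    attention_dim: int,
    n_prototypes: int,
    n_classes: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Seeded uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) weights, zero biases.

    Prototypes are initialised to zeros here; the trainer overwrites them with
    embeddings of randomly chosen training instances before the first step.
    """
    params: dict[str, np.ndarray] = {}
    u = hidden_size * (2 if bidirectional else 1)
    dirs = "fb" if bidirectional else "f"
    d_in = n_frame
    for layer in range(n_layers):
        for d in dirs:
            key = f"enc{layer}{d}"
            params[f"{key}_Wx"] = _uniform(rng, (4 * hidden_size, d_in), d_in)
            params[f"{key}_Wh"] = _uniform(rng, (4 * hidden_size, hidden_size), hidden_size)
            params[f"{key}_b"] = np.zeros(4 * hidden_size)
        d_in = u
    params["att_W"] = _uniform(rng, (u, attention_dim), u)
    params["att_b"] = np.zeros(attention_dim)
    params["att_V"] = _uniform(rng, (attention_dim,), attention_dim)
    params["proto"] = np.zeros((n_prototypes, u))
    params["head"] = _uniform(rng, (n_classes, n_prototypes), n_prototypes)
    return params


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# LSTM layers


def lstm_layer_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run one unidirectional LSTM layer over a batch.

    X : (B, T, D_in). Returns hidden states (B, T, H) and a cache for backprop.
    """
    B, T, _ = X.shape
    H = Wh.shape[1]
    pre = X @ Wx.T + b  # input contribution, all steps at once
    I = np.empty((B, T, H))
    F = np.empty((B, T, H))
    G = np.empty((B, T, H))
    O = np.empty((B, T, H))
    C = np.empty((B, T, H))
    TC = np.empty((B, T, H))
    Hout = np.empty((B, T, H))
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    for t in range(T):
        a = pre[:, t] + h @ Wh.T
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite hidden state at step {t}")
        I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g, o
        C[:, t], TC[:, t], Hout[:, t] = c, tc, h
    cache = {"X": X, "I": I, "F": F, "G": G, "O": O, "C": C, "TC": TC, "H": Hout,
             "Wx": Wx, "Wh": Wh}
    return Hout, cache


def lstm_layer_backward(dH: np.ndarray, cache: dict):
    """Backprop one LSTM layer. dH: (B, T, H) grads w.r.t. hidden outputs.

    Returns (dX, dWx, dWh, db).
    """
    X, Wx, Wh = cache["X"], cache["Wx"], cache["Wh"]
    I, F, G, O, C, TC, Hout = (cache[k] for k in ("I", "F", "G", "O", "C", "TC", "H"))
    B, T, H = dH.shape
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dX = np.empty_like(X)
    dh_carry = np.zeros((B, H))
    dc_carry = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev = Hout[:, t - 1] if t > 0 else np.zeros((B, H))
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
        dh = dH[:, t] + dh_carry
        do = dh * TC[:, t]
        dc = dc_carry + dh * O[:, t] * (1.0 - TC[:, t] ** 2)
        di = dc * G[:, t]
        df = dc * c_prev
        dg = dc * I[:, t]
        da = np.concatenate(
            [
                di * I[:, t] * (1.0 - I[:, t]),
                df * F[:, t] * (1.0 - F[:, t]),
                dg * (1.0 - G[:, t] ** 2),
                do * O[:, t] * (1.0 - O[:, t]),
            ],
            axis=1,
        )
        dWx += da.T @ X[:, t]
        dWh += da.T @ h_prev
        db += da.sum(axis=0)
        dX[:, t] = da @ Wx
        dh_carry = da @ Wh
        dc_carry = dc * F[:, t]
    return dX, dWx, dWh, db


def encoder_forward(params: dict, X: np.ndarray, n_layers: int, bidirectional: bool):
    """Stacked (bi)directional LSTM. X: (B, T, n). Returns H (B, T, u) and caches."""
    inp = X
    caches = []
    for layer in range(n_layers):
        key = f"enc{layer}f"
        Hf, cf = lstm_layer_forward(inp, params[f"{key}_Wx"], params[f"{key}_Wh"], params[f"{key}_b"])
        if bidirectional:
            key = f"enc{layer}b"
            Hb_rev, cb = lstm_layer_forward(
                inp[:, ::-1], params[f"{key}_Wx"], params[f"{key}_Wh"], params[f"{key}_b"]
            )
            out = np.concatenate([Hf, Hb_rev[:, ::-1]], axis=2)
        else:
            cb = None
            out = Hf
        caches.append((cf, cb))
        inp = out
    return inp, caches


def encoder_backward(dH: np.ndarray, caches: list, n_layers: int, bidirectional: bool):
    """Backprop the stacked encoder. Returns grads dict for enc* keys (input grad discarded)."""
    grads: dict[str, np.ndarray] = {}
    d_out = dH
    for layer in range(n_layers - 1, -1, -1):
        cf, cb = caches[layer]
        H = cf["Wh"].shape[1]
        if bidirectional:
            dXf, dWxf, dWhf, dbf = lstm_layer_backward(d_out[:, :, :H], cf)
            dXb_rev, dWxb, dWhb, dbb = lstm_layer_backward(d_out[:, ::-1, H:], cb)
            d_out = dXf + dXb_rev[:, ::-1]
            grads[f"enc{layer}b_Wx"] = dWxb
            grads[f"enc{layer}b_Wh"] = dWhb
            grads[f"enc{layer}b_b"] = dbb
        else:
            d_out, dWxf, dWhf, dbf = lstm_layer_backward(d_out, cf)
        grads[f"enc{layer}f_Wx"] = dWxf
        grads[f"enc{layer}f_Wh"] = dWhf
        grads[f"enc{layer}f_b"] = dbf
    return grads


# ---------------------------------------------------------------------------
# attention pooling


def attention_forward(H: np.ndarray, W: np.ndarray, b: np.ndarray, V: np.ndarray,
                      use_tanh: bool = False):
    """Additive attention pooling. H: (B, T, u) -> alpha (B, T), e (B, u)."""
    if H.shape[1] == 0:
        raise ValueError("attention requires at least one time step")
    A = H @ W + b  # (B, T, D)
    A2 = np.tanh(A) if use_tanh else A
    scores = A2 @ V  # (B, T)
    alpha = softmax(scores, axis=1)
    e = np.einsum("bt,btu->bu", alpha, H)
    cache = {"H": H, "A": A, "A2": A2, "alpha": alpha, "W": W, "V": V, "use_tanh": use_tanh}
    return alpha, e, cache


def attention_backward(de: np.ndarray, cache: dict):
    """Backprop attention pooling. Returns (dH, dW, db, dV)."""
    H, A, A2, alpha = cache["H"], cache["A"], cache["A2"], cache["alpha"]
    W, V, use_tanh = cache["W"], cache["V"], cache["use_tanh"]
    dalpha = np.einsum("bu,btu->bt", de, H)
    dH = alpha[:, :, None] * de[:, None, :]
    dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    dV = np.einsum("bt,btd->d", dscores, A2)
    dA2 = dscores[:, :, None] * V
    dA = dA2 * (1.0 - A2**2) if use_tanh else dA2
    dW = np.einsum("btu,btd->ud", H, dA)
    db = dA.sum(axis=(0, 1))
    dH += dA @ W.T
    return dH, dW, db, dV


# ---------------------------------------------------------------------------
# prototype layer + linear head


def prototype_forward(e: np.ndarray, P: np.ndarray, Whead: np.ndarray,
                      squared: bool = False):
    """Distances, similarities, logits. e: (B, u). Returns (d, s, z, cache)."""
    diff = e[:, None, :] - P[None, :, :]  # (B, K, u)
    dist2 = np.einsum("bku,bku->bk", diff, diff)
    d = dist2 if squared else np.sqrt(dist2)
    s = np.exp(-d)
    z = s @ Whead.T
    cache = {"diff": diff, "d": d, "s": s, "Whead": Whead, "squared": squared}
    return d, s, z, cache


def prototype_backward(dz: np.ndarray, cache: dict):
    """Backprop dz (B, C) through head + similarities + distances.

    Returns (de, dP, dWhead). At d == 0 the unsquared distance has no gradient;
    the subgradient 0 is used.
    """
    diff, d, s, Whead = cache["diff"], cache["d"], cache["s"], cache["Whead"]
    dWhead = dz.T @ s
    ds = dz @ Whead  # (B, K)
    dd = -s * ds
    if cache["squared"]:
        coef = 2.0 * dd
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            coef = np.where(d > 0, dd / np.where(d > 0, d, 1.0), 0.0)
    de = np.einsum("bk,bku->bu", coef, diff)
    dP = -np.einsum("bk,bku->ku", coef, diff)
    return de, dP, dWhead


# ---------------------------------------------------------------------------
# optimisation utilities


class Adam:
    """Adaptive-moment gradient optimiser over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """In-place global-norm gradient clipping. Returns the pre-clip norm."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total
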