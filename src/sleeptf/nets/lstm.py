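"""LSTM recurrence: per-gate reference step, fused layer, and BiLSTM.

The per-gate recurrence is

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)          forget gate
    i_t = sigma(W_i x_t + U_i h_{t-1} + b_i)          input gate
    C_t = f_t * C_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    O_t = sigma(W_o x_t + U_o h_{t-1} + b_o)          output gate
    h_t = O_t * tanh(C_t)

with sigmoid gate activations and tanh cell/output activations.
``lstm_step`` implements this literally, gate by gate, and serves as the
oracle that the vectorized :class:`LSTMLayer` must match.  A BiLSTM runs a
second LSTM with its own parameters over the reversed sequence and
concatenates both outputs position-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LSTMParams", "LSTMState", "lstm_step", "lstm_forward", "bilstm_forward", "LSTMLayer", "BiLSTMLayer"]

_GATES = ("i", "f", "c", "o")  # packing order for the fused matrices


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class LSTMParams:
    """Per-gate parameters: W_* (H x D), U_* (H x H), b_* (H,)."""

    W: dict[str, np.ndarray]  # input weights, keys i/f/c/o
    U: dict[str, np.ndarray]  # recurrent weights
    b: dict[str, np.ndarray]  # biases

    def __post_init__(self) -> None:
        H, D = self.hidden_size, self.input_size
        for g in _GATES:
            if self.W[g].shape != (H, D) or self.U[g].shape != (H, H) or self.b[g].shape != (H,):
                raise ValueError(f"inconsistent parameter shapes for gate {g!r}")

    @property
    def hidden_size(self) -> int:
        return self.W["i"].shape[0]

    @property
    def input_size(self) -> int:
        return self.W["i"].shape[1]

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LSTMParams":
        return cls(
            W={g: np.zeros((hidden_size, input_size)) for g in _GATES},
            U={g: np.zeros((hidden_size, hidden_size)) for g in _GATES},
            b={g: np.zeros(hidden_size) for g in _GATES},
        )

    @classmethod
    def random(cls, input_size: int, hidden_size: int, rng: np.random.Generator,
               scale: float | None = None) -> "LSTMParams":
        s_in = scale if scale is not None else 1.0 / np.sqrt(input_size)
        s_rec = scale if scale is not None else 1.0 / np.sqrt(hidden_size)
        return cls(
            W={g: rng.uniform(-s_in, s_in, (hidden_size, input_size)) for g in _GATES},
            U={g: rng.uniform(-s_rec, s_rec, (hidden_size, hidden_size)) for g in _GATES},
            b={g: np.zeros(hidden_size) for g in _GATES},
        )

    @classmethod
    def from_packed(cls, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray) -> "LSTMParams":
        H = Wx.shape[0] // 4
        return cls(
            W={g: Wx[k * H : (k + 1) * H] for k, g in enumerate(_GATES)},
            U={g: Wh[k * H : (k + 1) * H] for k, g in enumerate(_GATES)},
            b={g: b[k * H : (k + 1) * H] for k, g in enumerate(_GATES)},
        )

    def packed(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Wx, Wh, b) stacked in gate order i, f, c, o -> (4H x D), (4H x H), (4H,)."""
        Wx = np.concatenate([self.W[g] for g in _GATES], axis=0)
        Wh = np.concatenate([self.U[g] for g in _GATES], axis=0)
        b = np.concatenate([self.b[g] for g in _GATES], axis=0)
        return Wx, Wh, b


@dataclass(frozen=True)
class LSTMState:
    """Hidden output h and cell state C of one LSTM unit."""

    h: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_size), C=np.zeros(hidden_size))


def lstm_step(x_t: np.ndarray, prev: LSTMState, params: LSTMParams) -> LSTMState:
    """One recurrence step, written gate by gate (the reference path)."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(
            f"x_t has shape {x_t.shape}, expected ({params.input_size},)"
        )
    if prev.h.shape != (params.hidden_size,) or prev.C.shape != (params.hidden_size,):
        raise ValueError("state dimensions do not match the parameters")
    W, U, b = params.W, params.U, params.b
    f_t = _sigmoid(W["f"] @ x_t + U["f"] @ prev.h + b["f"])
    i_t = _sigmoid(W["i"] @ x_t + U["i"] @ prev.h + b["i"])
    C_t = f_t * prev.C + i_t * np.tanh(W["c"] @ x_t + U["c"] @ prev.h + b["c"])
    O_t = _sigmoid(W["o"] @ x_t + U["o"] @ prev.h + b["o"])
    h_t = O_t * np.tanh(C_t)
    return LSTMState(h=h_t, C=C_t)


def lstm_forward(seq: np.ndarray, params: LSTMParams) -> np.ndarray:
    """Run the recurrence over a (T, D) sequence from a zero state -> (T, H)."""
    state = LSTMState.zeros(params.hidden_size)
    out = np.empty((len(seq), params.hidden_size))
    for t, x_t in enumerate(seq):
        state = lstm_step(x_t, state, params)
        out[t] = state.h
    return out


def bilstm_forward(seq: np.ndarray, fwd: LSTMParams, bwd: LSTMParams) -> np.ndarray:
    """Bidirectional pass over a (T, D) sequence -> (T, 2H).

    Position t carries [forward h_t ; backward h'_t] where the backward
    LSTM consumes the sequence in reverse time order.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("seq must be a nonempty (T, D) array")
    h_f = lstm_forward(seq, fwd)
    h_b = lstm_forward(seq[::-1], bwd)[::-1]
    return np.concatenate([h_f, h_b], axis=1)


class LSTMLayer:
    """Fused batch LSTM over (N, T, D) with BPTT.

    Packs the four gates into single matrices for speed; numerically
    equivalent to iterating :func:`lstm_step` (tested).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator) -> None:
        p = LSTMParams.random(input_size, hidden_size, rng)
        Wx, Wh, b = p.packed()
        self.params = {
            "Wx": Wx.astype(np.float32),
            "Wh": Wh.astype(np.float32),
            "b": b.astype(np.float32),
        }
        self.grads: dict[str, np.ndarray] = {}
        self.H = hidden_size
        self.D = input_size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, T, D = x.shape
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        out = np.empty((N, T, H), dtype=x.dtype)
        cache = []
        xa = x @ Wx.T + b  # (N, T, 4H): input contributions precomputed
        for t in range(T):
            a = xa[:, t] + h @ Wh.T
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t] = h
            cache.append((i, f, g, o, c_prev, tc, h_prev))
        self._cache = (x, cache)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        N, T, D = x.shape
        H = self.H
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = np.zeros((N, H), dtype=x.dtype)
        dc_next = np.zeros((N, H), dtype=x.dtype)
        da = np.empty((N, 4 * H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tc, h_prev = cache[t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da[:, :H] = di * i * (1 - i)
            da[:, H : 2 * H] = df * f * (1 - f)
            da[:, 2 * H : 3 * H] = dg * (1 - g**2)
            da[:, 3 * H :] = do * o * (1 - o)
            dWx += da.T @ x[:, t]
            dWh += da.T @ h_prev
            db += da.sum(axis=0)
            dx[:, t] = da @ Wx
            dh_next = da @ Wh
            dc_next = dc * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class BiLSTMLayer:
    """Concatenated forward/backward LSTM over (N, T, D) -> (N, T, 2H)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator) -> None:
        self.fwd = LSTMLayer(input_size, hidden_size, rng)
        self.bwd = LSTMLayer(input_size, hidden_size, rng)
        self.H = hidden_size

    @property
    def params(self):  # exposed for the optimizer via sublayers
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out_f = self.fwd.forward(x, train)
        out_b = self.bwd.forward(x[:, ::-1], train)[:, ::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.H
        dx_f = self.fwd.backward(dout[:, :, :H])
        dx_b = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dx_f + np.ascontiguousarray(dx_b)
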