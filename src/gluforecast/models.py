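"""Forecasting architectures: the hybrid Transformer-LSTM and five
recurrent baselines (RNN, GRU, LSTM, stacked LSTM, bidirectional LSTM).

Two layers of API:

* functional numpy primitives (`positional_encoding`, `lstm_cell_step`,
  `lstm_forward`) that state the recurrences exactly and serve as oracles;
* trainable `Module` models built on the autodiff engine, whose LSTM path
  is weight-compatible with the functional primitives.

All six model kinds share the same skeleton: per-step linear embedding ->
core -> feature vector -> linear head -> scalar forecast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Dropout,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    concat,
    softmax,
)
from .errors import ParameterError

MODEL_KINDS = ("rnn", "gru", "lstm", "stacked_lstm", "bilstm", "transformer_lstm")


# ----------------------------------------------------------------------
# Functional primitives
# ----------------------------------------------------------------------


def positional_encoding(L: int, d_model: int) -> np.ndarray:
    """Sinusoidal position table: PE[pos, 2i] = sin(pos / 10000^(2i/d)),
    PE[pos, 2i+1] = cos(pos / 10000^(2i/d))."""
    if d_model % 2 != 0:
        raise ParameterError("d_model must be even for sinusoidal encoding")
    if L < 1:
        raise ParameterError("L must be >= 1")
    pos = np.arange(L, dtype=np.float64)[:, None]
    i = np.arange(d_model // 2, dtype=np.float64)[None, :]
    angles = pos / np.power(10000.0, 2.0 * i / d_model)
    table = np.empty((L, d_model))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles)
    return table


@dataclass
class LSTMCellParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_O: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_O: np.ndarray

    def __post_init__(self):
        shape = self.W_f.shape
        for name in ("W_i", "W_C", "W_O"):
            if getattr(self, name).shape != shape:
                raise ParameterError("all gate weight matrices must share shape")
        h = shape[0]
        for name in ("b_f", "b_i", "b_C", "b_O"):
            if getattr(self, name).shape != (h,):
                raise ParameterError("bias length must equal hidden size")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    @classmethod
    def random(
        cls, hidden_size: int, input_size: int, rng: np.random.Generator
    ) -> "LSTMCellParams":
        bound = 1.0 / np.sqrt(hidden_size + input_size)
        w = lambda: rng.uniform(-bound, bound, (hidden_size, hidden_size + input_size))
        b = lambda: rng.uniform(-bound, bound, hidden_size)
        return cls(w(), w(), w(), w(), b(), b(), b(), b())


@dataclass
class LSTMCellState:
    h: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        if self.h.shape != self.C.shape:
            raise ParameterError("h and C must have equal length")

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMCellState":
        return cls(np.zeros(hidden_size), np.zeros(hidden_size))


@dataclass
class GateActivations:
    f_t: np.ndarray
    i_t: np.ndarray
    O_t: np.ndarray
    C_tilde: np.ndarray


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_cell_step(
    x_t: np.ndarray, prev: LSTMCellState, p: LSTMCellParams
) -> tuple[LSTMCellState, GateActivations]:
    """One LSTM recurrence:

        f_t = sigmoid(W_f [h, x] + b_f)        (forget gate)
        i_t = sigmoid(W_i [h, x] + b_i)        (input gate)
        C~  = tanh(W_C [h, x] + b_C)           (candidate cell)
        C_t = f_t * C_{t-1} + i_t * C~
        O_t = sigmoid(W_O [h, x] + b_O)        (output gate)
        h_t = O_t * tanh(C_t)
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    if x_t.shape != (p.input_size,):
        raise ParameterError(
            f"expected input of shape ({p.input_size},), got {x_t.shape}"
        )
    z = np.concatenate([prev.h, x_t])
    f_t = _sigmoid(p.W_f @ z + p.b_f)
    i_t = _sigmoid(p.W_i @ z + p.b_i)
    C_tilde = np.tanh(p.W_C @ z + p.b_C)
    C_t = f_t * prev.C + i_t * C_tilde
    O_t = _sigmoid(p.W_O @ z + p.b_O)
    h_t = O_t * np.tanh(C_t)
    return LSTMCellState(h_t, C_t), GateActivations(f_t, i_t, O_t, C_tilde)


def lstm_forward(
    seq: np.ndarray, p: LSTMCellParams, init: LSTMCellState | None = None
) -> np.ndarray:
    """Left fold of `lstm_cell_step` over time; returns the (T, hidden)
    matrix of hidden states."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ParameterError("seq must be a nonempty (T, d) matrix")
    state = init or LSTMCellState.zeros(p.hidden_size)
    out = np.empty((seq.shape[0], p.hidden_size))
    for t in range(seq.shape[0]):
        state, _ = lstm_cell_step(seq[t], state, p)
        out[t] = state.h
    return out


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class HybridConfig:
    d_model: int = 16
    n_heads: int = 2
    n_encoder_layers: int = 2
    ffn_width: int = 32
    lstm_hidden: int = 32
    lstm_layers: int = 1
    dropout: float = 0.1
    lookback: int = 12
    pooling: str = "mean"  # {"mean", "last"} for the transformer branch

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ParameterError("d_model must be divisible by n_heads")
        for name in ("d_model", "n_heads", "n_encoder_layers", "ffn_width",
                     "lstm_hidden", "lstm_layers", "lookback"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ParameterError("dropout must be in [0, 1)")
        if self.pooling not in ("mean", "last"):
            raise ParameterError("pooling must be 'mean' or 'last'")


# ----------------------------------------------------------------------
# Trainable layers
# ----------------------------------------------------------------------


class LSTMLayer(Module):
    """Batched LSTM over (B, T, d) sequences, weight-compatible with
    `LSTMCellParams` (gate weights act on [h, x])."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size + input_size)
        # stored transposed: (hidden+input, hidden), so forward is z @ W + b
        def w():
            return Tensor(
                rng.uniform(-bound, bound, (hidden_size + input_size, hidden_size)),
                requires_grad=True,
            )

        def b():
            return Tensor(rng.uniform(-bound, bound, hidden_size), requires_grad=True)

        self.Wf, self.Wi, self.Wc, self.Wo = w(), w(), w(), w()
        self.bf, self.bi, self.bc, self.bo = b(), b(), b(), b()

    def cell_params(self) -> LSTMCellParams:
        """Gate-matrix view of the weights (for oracle comparisons)."""
        return LSTMCellParams(
            self.Wf.data.T.copy(), self.Wi.data.T.copy(),
            self.Wc.data.T.copy(), self.Wo.data.T.copy(),
            self.bf.data.copy(), self.bi.data.copy(),
            self.bc.data.copy(), self.bo.data.copy(),
        )

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        c = Tensor(np.zeros((B, self.hidden_size)))
        hs: list[Tensor] = []
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            z = concat([h, x[:, t, :]], axis=1)
            f = (z @ self.Wf + self.bf).sigmoid()
            i = (z @ self.Wi + self.bi).sigmoid()
            ctil = (z @ self.Wc + self.bc).tanh()
            c = f * c + i * ctil
            o = (z @ self.Wo + self.bo).sigmoid()
            h = o * c.tanh()
            hs.append(h)
        if reverse:
            hs.reverse()
        from .autodiff import stack

        return stack(hs, axis=1)  # (B, T, hidden)


class GRULayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size + input_size)

        def w():
            return Tensor(
                rng.uniform(-bound, bound, (hidden_size + input_size, hidden_size)),
                requires_grad=True,
            )

        def b():
            return Tensor(rng.uniform(-bound, bound, hidden_size), requires_grad=True)

        self.Wz, self.Wr, self.Wh = w(), w(), w()
        self.bz, self.br, self.bh = b(), b(), b()

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        hs = []
        for t in range(T):
            xt = x[:, t, :]
            zcat = concat([h, xt], axis=1)
            z = (zcat @ self.Wz + self.bz).sigmoid()
            r = (zcat @ self.Wr + self.br).sigmoid()
            hcat = concat([r * h, xt], axis=1)
            htil = (hcat @ self.Wh + self.bh).tanh()
            h = (1.0 - z) * h + z * htil
            hs.append(h)
        from .autodiff import stack

        return stack(hs, axis=1)


class RNNLayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        bound = 1.0 / np.sqrt(hidden_size + input_size)
        self.W = Tensor(
            rng.uniform(-bound, bound, (hidden_size + input_size, hidden_size)),
            requires_grad=True,
        )
        self.b = Tensor(rng.uniform(-bound, bound, hidden_size), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden_size)))
        hs = []
        for t in range(T):
            h = (concat([h, x[:, t, :]], axis=1) @ self.W + self.b).tanh()
            hs.append(h)
        from .autodiff import stack

        return stack(hs, axis=1)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ParameterError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, d = x.shape

        def split(t: Tensor) -> Tensor:  # (B, L, d) -> (B, h, L, d_k)
            return t.reshape(B, L, self.n_heads, self.d_k).swapaxes(1, 2)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        attn = softmax(scores, axis=-1)          # no causal mask
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, d)
        return self.out(ctx)


class EncoderLayer(Module):
    """Post-norm transformer encoder block: residual then LayerNorm around
    both the attention and the position-wise FFN."""

    def __init__(self, cfg: HybridConfig, rng: np.random.Generator):
        super().__init__()
        self.mha = MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng)
        self.ln1 = LayerNorm(cfg.d_model)
        self.ff1 = Linear(cfg.d_model, cfg.ffn_width, rng)
        self.ff2 = Linear(cfg.ffn_width, cfg.d_model, rng)
        self.ln2 = LayerNorm(cfg.d_model)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop(self.mha(x)))
        x = self.ln2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class TransformerEncoder(Module):
    def __init__(self, cfg: HybridConfig, rng: np.random.Generator):
        super().__init__()
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_encoder_layers)]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def transformer_encoder(
    embedded: np.ndarray, cfg: HybridConfig, weights: TransformerEncoder
) -> np.ndarray:
    """Functional wrapper: run an (L, d_model) matrix (positional encoding
    already added) through an encoder stack in evaluation mode."""
    embedded = np.asarray(embedded, dtype=np.float64)
    if embedded.ndim != 2 or embedded.shape[1] != cfg.d_model:
        raise ParameterError("embedded must be (L, d_model)")
    was_training = weights.training
    weights.eval()
    out = weights(Tensor(embedded[None, :, :])).data[0]
    if was_training:
        weights.train()
    return out


# ----------------------------------------------------------------------
# Full models
# ----------------------------------------------------------------------


class _ForecasterBase(Module):
    kind: str = "base"

    def __init__(self, cfg: HybridConfig):
        super().__init__()
        self.cfg = cfg

    def set_dropout_rng(self, rng: np.random.Generator | None) -> None:
        for v in vars(self).values():
            for m in _iter_dropouts(v):
                m.rng = rng

    def predict_batch(self, windows: np.ndarray) -> np.ndarray:
        """Deterministic (eval-mode) forward over an (n, L) array."""
        was_training = self.training
        self.eval()
        out = self(Tensor(np.asarray(windows, dtype=np.float64))).data
        if was_training:
            self.train()
        return out


def _iter_dropouts(obj):
    if isinstance(obj, Dropout):
        yield obj
    elif isinstance(obj, Module):
        for v in vars(obj).values():
            yield from _iter_dropouts(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_dropouts(v)


class HybridForecaster(_ForecasterBase):
    """Transformer encoder and LSTM in parallel over the embedded window;
    the pooled encoder output and the final LSTM hidden state are
    concatenated and mapped to the scalar forecast."""

    kind = "transformer_lstm"

    def __init__(self, cfg: HybridConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.embed = Linear(1, cfg.d_model, rng)
        self.pe = Tensor(positional_encoding(cfg.lookback, cfg.d_model))
        self.encoder = TransformerEncoder(cfg, rng)
        sizes = [cfg.d_model] + [cfg.lstm_hidden] * cfg.lstm_layers
        self.lstm = [
            LSTMLayer(sizes[i], sizes[i + 1], rng) for i in range(cfg.lstm_layers)
        ]
        self.head = Linear(cfg.d_model + cfg.lstm_hidden, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L = x.shape
        if L != self.cfg.lookback:
            raise ParameterError(f"expected windows of length {self.cfg.lookback}")
        e = self.embed(x.reshape(B, L, 1)) + self.pe
        z = self.encoder(e)
        if self.cfg.pooling == "mean":
            branch_a = z.mean(axis=1)
        else:
            branch_a = z[:, -1, :]
        h = z
        for layer in self.lstm:
            h = layer(h)
        branch_b = h[:, -1, :]
        return self.head(concat([branch_a, branch_b], axis=1)).reshape(B)


class RecurrentForecaster(_ForecasterBase):
    """Shared skeleton for the five baselines."""

    def __init__(self, kind: str, cfg: HybridConfig, rng: np.random.Generator):
        super().__init__(cfg)
        self.kind = kind
        d, hid = cfg.d_model, cfg.lstm_hidden
        self.embed = Linear(1, d, rng)
        self.backward_core = None
        if kind == "rnn":
            self.core = [RNNLayer(d, hid, rng)]
        elif kind == "gru":
            self.core = [GRULayer(d, hid, rng)]
        elif kind == "lstm":
            self.core = [LSTMLayer(d, hid, rng)]
        elif kind == "stacked_lstm":
            self.core = [LSTMLayer(d, hid, rng), LSTMLayer(hid, hid, rng)]
        elif kind == "bilstm":
            self.core = [LSTMLayer(d, hid, rng)]
            self.backward_core = LSTMLayer(d, hid, rng)
        else:
            raise ParameterError(f"unknown model kind {kind!r}")
        feat = 2 * hid if kind == "bilstm" else hid
        self.head = Linear(feat, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L = x.shape
        if L != self.cfg.lookback:
            raise ParameterError(f"expected windows of length {self.cfg.lookback}")
        h = self.embed(x.reshape(B, L, 1))
        if self.backward_core is not None:  # bilstm
            fwd = self.core[0](h)[:, -1, :]
            bwd = self.backward_core(h, reverse=True)[:, 0, :]
            feat = concat([fwd, bwd], axis=1)
        else:
            for layer in self.core:
                h = layer(h)
            feat = h[:, -1, :]
        return self.head(feat).reshape(B)


def build_model(kind: str, cfg: HybridConfig, seed: int = 0) -> _ForecasterBase:
    """Construct any of the six model kinds with seeded initialization."""
    if kind not in MODEL_KINDS:
        raise ParameterError(
            f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}"
        )
    rng = np.random.default_rng(seed)
    if kind == "transformer_lstm":
        return HybridForecaster(cfg, rng)
    return RecurrentForecaster(kind, cfg, rng)


def hybrid_forward(window: np.ndarray, model: HybridForecaster) -> float:
    """Evaluation-mode forecast for a single (already scaled) window."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (model.cfg.lookback,):
        raise ParameterError(
            f"window must have length {model.cfg.lookback}, got {window.shape}"
        )
    return float(model.predict_batch(window[None, :])[0])
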