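"""Neural layers used by the language- and speech-stream classifiers.

All layers operate on :class:`~adspeech.nn.autograd.Tensor` and are initialized
from an explicit ``numpy.random.Generator`` so runs are reproducible bit-for-bit.
Sequence layers take an optional boolean mask (batch x time) and honour the
contract that masked positions cannot influence the output.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate

__all__ = [
    "Module",
    "Dense",
    "Conv1D",
    "LSTM",
    "BiLSTM",
    "GRU",
    "AttentionPool",
    "Dropout",
    "bce_with_logits",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Base class: recursively collects parameters from attributes."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        params.extend(v.parameters())
                    elif isinstance(v, Tensor) and v.requires_grad:
                        params.append(v)
        return params

    def set_training(self, flag: bool):
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        v.set_training(flag)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch when restoring weights")
        for p, a in zip(params, arrays):
            p.data = a.copy()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.W = _glorot(rng, n_in, n_out)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        z = x @ self.W + self.b
        if self.activation == "relu":
            return z.relu()
        if self.activation == "tanh":
            return z.tanh()
        if self.activation == "sigmoid":
            return z.sigmoid()
        return z


class Conv1D(Module):
    """Temporal convolution over (batch, time, channels), 'same' zero padding."""

    def __init__(self, n_in: int, n_filters: int, kernel_size: int,
                 rng: np.random.Generator):
        self.kernel_size = kernel_size
        self.W = [_glorot(rng, n_in * kernel_size, n_filters, shape=(n_in, n_filters))
                  for _ in range(kernel_size)]
        self.b = Tensor(np.zeros(n_filters), requires_grad=True)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        if mask is not None:
            x = x * mask[:, :, None].astype(float)
        left = (self.kernel_size - 1) // 2
        out = None
        for j, Wj in enumerate(self.W):
            off = j - left
            lo, hi = max(0, -off), min(T, T - off)
            piece = x[:, lo + off:hi + off, :] @ Wj          # aligned window
            # pad back to T along time with zeros (constant shift)
            pad_pre = np.zeros((B, lo, Wj.shape[1]))
            pad_post = np.zeros((B, T - hi, Wj.shape[1]))
            pieces = []
            if lo:
                pieces.append(Tensor(pad_pre))
            pieces.append(piece)
            if T - hi:
                pieces.append(Tensor(pad_post))
            term = concatenate(pieces, axis=1) if len(pieces) > 1 else piece
            out = term if out is None else out + term
        out = out + self.b
        if mask is not None:
            out = out * mask[:, :, None].astype(float)
        return out


class _RecurrentBase(Module):
    def __init__(self, n_in: int, n_hidden: int, n_gates: int,
                 rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wx = _glorot(rng, n_in, n_gates * n_hidden,
                          shape=(n_in, n_gates * n_hidden))
        self.Wh = _glorot(rng, n_hidden, n_gates * n_hidden,
                          shape=(n_hidden, n_gates * n_hidden))
        self.b = Tensor(np.zeros(n_gates * n_hidden), requires_grad=True)

    @staticmethod
    def _mask_step(h_new: Tensor, h_old: Tensor, m_t: np.ndarray) -> Tensor:
        # masked timestep: carry the previous hidden state through unchanged
        m = m_t[:, None].astype(float)
        return h_new * m + h_old * (1.0 - m)


class GRU(_RecurrentBase):
    """Gated recurrent unit over (batch, time, features); returns all states."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__(n_in, n_hidden, 3, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.n_hidden
        if mask is None:
            mask = np.ones((B, T), dtype=bool)
        h = Tensor(np.zeros((B, H)))
        xg = x @ self.Wx + self.b                 # (B, T, 3H) input projections
        states: list[Tensor] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            g_x = xg[:, t, :]
            g_h = h @ self.Wh
            z = (g_x[:, :H] + g_h[:, :H]).sigmoid()
            r = (g_x[:, H:2 * H] + g_h[:, H:2 * H]).sigmoid()
            n = (g_x[:, 2 * H:] + r * g_h[:, 2 * H:]).tanh()
            h_new = (1.0 - z) * n + z * h
            h = self._mask_step(h_new, h, mask[:, t])
            states[t] = h.reshape(B, 1, H)
        return concatenate(states, axis=1)


class LSTM(_RecurrentBase):
    """Unidirectional LSTM; returns all hidden states (batch, time, hidden)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__(n_in, n_hidden, 4, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None,
                 reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.n_hidden
        if mask is None:
            mask = np.ones((B, T), dtype=bool)
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        xg = x @ self.Wx + self.b
        states: list[Tensor] = [None] * T
        order = range(T - 1, -1, -1) if reverse else range(T)
        for t in order:
            g = xg[:, t, :] + h @ self.Wh
            i = g[:, :H].sigmoid()
            f = g[:, H:2 * H].sigmoid()
            o = g[:, 2 * H:3 * H].sigmoid()
            u = g[:, 3 * H:].tanh()
            c_new = f * c + i * u
            h_new = o * c_new.tanh()
            c = self._mask_step(c_new, c, mask[:, t])
            h = self._mask_step(h_new, h, mask[:, t])
            states[t] = h.reshape(B, 1, H)
        return concatenate(states, axis=1)


class BiLSTM(Module):
    """Forward + backward LSTM, hidden states concatenated per timestep."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng)

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        return concatenate([self.fwd(x, mask), self.bwd(x, mask, reverse=True)],
                           axis=2)


class AttentionPool(Module):
    """Additive attention over hidden states with a learned score vector.

    score_t = v . tanh(W h_t); weights = softmax over unmasked steps;
    output = sum_t weight_t * h_t.
    """

    def __init__(self, n_hidden: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_hidden, n_hidden)
        self.v = _glorot(rng, n_hidden, 1, shape=(n_hidden, 1))

    def __call__(self, states: Tensor, mask: np.ndarray | None = None) -> Tensor:
        B, T, H = states.shape
        if mask is None:
            mask = np.ones((B, T), dtype=bool)
        if not mask.any(axis=1).all():
            raise ValueError("attention_pool requires >=1 unmasked timestep per row")
        scores = (states @ self.W).tanh() @ self.v          # (B, T, 1)
        scores = scores.reshape(B, T)
        m = mask.astype(float)
        shift = (scores.data * m).max(axis=1, keepdims=True)  # detached for stability
        e = ((scores - shift) * m).exp() * m
        weights = e / e.sum(axis=1, keepdims=True)
        return (states * weights.reshape(B, T, 1)).sum(axis=1)

    def weights(self, states: Tensor, mask: np.ndarray | None = None) -> np.ndarray:
        B, T, H = states.shape
        if mask is None:
            mask = np.ones((B, T), dtype=bool)
        scores = ((states @ self.W).tanh() @ self.v).reshape(B, T)
        m = mask.astype(float)
        shift = (scores.data * m).max(axis=1, keepdims=True)
        e = np.exp((scores.data - shift)) * m
        return e / e.sum(axis=1, keepdims=True)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.shape) < keep).astype(float) / keep
        return x * mask


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logit."""
    y = np.asarray(labels, dtype=float)
    return (logits.softplus() - logits * y).mean()
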