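"""Neural-network layers built on the autograd engine.

All sequence layers use a channels-last ``(batch, length, features)``
layout.  Parameter shapes and counts follow the conventions of mainstream
deep-learning libraries (LSTM with separate input-to-hidden and
hidden-to-hidden biases; transformer encoder layers with pre-softmax
scaling, two LayerNorms and a two-layer feed-forward block), so parameter
totals are directly comparable.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

NEG_INF = -1e9


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, RNG plumbing."""

    def __init__(self):
        self._training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            for item in (v if isinstance(v, (list, tuple)) else [v]):
                if isinstance(item, Module):
                    yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                for item in (v if isinstance(v, (list, tuple)) else [v]):
                    if isinstance(item, Parameter):
                        params.append(item)
        return params

    def named_parameters(self):
        out = []

        def visit(mod, prefix):
            for name, v in mod.__dict__.items():
                items = v if isinstance(v, (list, tuple)) else [v]
                for i, item in enumerate(items):
                    tag = f"{prefix}{name}" + (
                        f".{i}" if isinstance(v, (list, tuple)) else ""
                    )
                    if isinstance(item, Parameter):
                        out.append((tag, item))
                    elif isinstance(item, Module):
                        visit(item, tag + ".")

        visit(self, "")
        return out

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m._training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        named = dict(self.named_parameters())
        if set(named) != set(state):
            missing = set(named) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in named.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: model {p.data.shape} vs "
                    f"snapshot {state[name].shape}"
                )
            p.data = state[name].astype(np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.weight = Parameter(_xavier(rng, in_features, out_features,
                                        (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Embedding(Module):
    def __init__(self, num_embeddings, dim, rng):
        super().__init__()
        self.weight = Parameter(rng.normal(0, 0.1, size=(num_embeddings, dim)))

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(idx, dtype=np.int64))


class PReLU(Module):
    """Parametric ReLU with one slope per channel (last axis)."""

    def __init__(self, num_parameters: int, init: float = 0.25):
        super().__init__()
        self.weight = Parameter(np.full(num_parameters, init))

    def forward(self, x: Tensor) -> Tensor:
        pos = x.relu()
        neg = (x * -1.0).relu() * -1.0
        return pos + neg * self.weight


class Dropout(Module):
    def __init__(self, p: float, rng):
        super().__init__()
        self.p = float(p)
        self._rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self._training or self.p <= 0:
            return x
        mask = (self._rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class LayerNorm(Module):
    def __init__(self, dim, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Conv1d(Module):
    """Same-padded 1-D convolution over the length axis, channels last.

    Implemented as a sum of shifted linear maps; odd kernel sizes only so
    the output length equals the input length.
    """

    def __init__(self, in_channels, out_channels, kernel_size, rng, bias=True):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for same padding")
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_xavier(
            rng, fan_in, out_channels, (kernel_size, in_channels, out_channels)
        ))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        b, length, cin = x.shape
        half = self.kernel_size // 2
        pad = Tensor(np.zeros((b, half, cin)))
        xp = Tensor.cat([pad, x, pad], axis=1)
        out = None
        for j in range(self.kernel_size):
            term = xp[:, j:j + length, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias if self.bias is not None else out


def _reverse_by_length(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Flip each sequence within its true length; padding stays in place."""
    b, L, _ = x.shape
    t = np.arange(L)[None, :]
    lens = np.asarray(lengths)[:, None]
    rev = np.where(t < lens, lens - 1 - t, t)
    batch = np.repeat(np.arange(b)[:, None], L, axis=1)
    return x[batch, rev]


class LSTM(Module):
    """Multi-layer (bi)directional LSTM, channels last.

    The reverse direction flips each sequence by its true length so that
    outputs at real positions are independent of trailing padding.
    """

    def __init__(self, input_size, hidden_size, num_layers, rng,
                 bidirectional=True):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.weights = []
        ndir = 2 if bidirectional else 1
        for layer in range(num_layers):
            in_sz = input_size if layer == 0 else hidden_size * ndir
            for _ in range(ndir):
                w_ih = Parameter(_xavier(rng, in_sz, 4 * hidden_size,
                                         (in_sz, 4 * hidden_size)))
                w_hh = Parameter(_xavier(rng, hidden_size, 4 * hidden_size,
                                         (hidden_size, 4 * hidden_size)))
                b_ih = Parameter(np.zeros(4 * hidden_size))
                b_hh = Parameter(np.zeros(4 * hidden_size))
                self.weights.extend([w_ih, w_hh, b_ih, b_hh])

    def _run_direction(self, x: Tensor, widx: int) -> Tensor:
        w_ih, w_hh, b_ih, b_hh = self.weights[widx:widx + 4]
        b, L, _ = x.shape
        h = Tensor(np.zeros((b, self.hidden_size)))
        c = Tensor(np.zeros((b, self.hidden_size)))
        H = self.hidden_size
        outs = []
        pre_x = x @ w_ih + b_ih  # (b, L, 4H): input projections for all steps
        for t in range(L):
            gates = pre_x[:, t, :] + h @ w_hh + b_hh
            i = gates[:, :H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return Tensor.stack(outs, axis=1)

    def forward(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        ndir = 2 if self.bidirectional else 1
        for layer in range(self.num_layers):
            base = layer * ndir * 4
            fwd = self._run_direction(x, base)
            if self.bidirectional:
                x_rev = _reverse_by_length(x, lengths)
                bwd = self._run_direction(x_rev, base + 4)
                bwd = _reverse_by_length(bwd, lengths)
                x = Tensor.cat([fwd, bwd], axis=-1)
            else:
                x = fwd
        return x


class MultiHeadAttention(Module):
    def __init__(self, dim, num_heads, rng):
        super().__init__()
        if dim % num_heads:
            raise ValueError("dim must be divisible by num_heads")
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        b, L, d = x.shape
        h, hd = self.num_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, L, h, hd).swapaxes(1, 2)  # (b, h, L, hd)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(hd))
        bias = np.where(pad_mask[:, None, None, :], 0.0, NEG_INF)
        attn = (scores + bias).softmax(axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(b, L, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: MHA + residual/LN, FFN + residual/LN."""

    def __init__(self, dim, num_heads, ffn_dim, dropout, rng):
        super().__init__()
        self.attn = MultiHeadAttention(dim, num_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_dim, rng)
        self.fc2 = Linear(ffn_dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.drop = Dropout(dropout, rng)

    def forward(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, pad_mask)))
        x = self.ln2(x + self.drop(self.fc2(self.drop(self.fc1(x).relu()))))
        return x


def sinusoidal_positions(length: int, dim: int) -> np.ndarray:
    """Fixed sinusoidal positional encoding matrix (length, dim)."""
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angle)
    enc[:, 1::2] = np.cos(angle[:, : dim - dim // 2])
    return enc


def masked_sum(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Sum over the length axis, ignoring padded positions."""
    L = x.shape[1]
    mask = (np.arange(L)[None, :] < np.asarray(lengths)[:, None]).astype(float)
    return (x * mask[:, :, None]).sum(axis=1)
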