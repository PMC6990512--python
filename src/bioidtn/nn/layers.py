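"""Neural building blocks: linear maps, embeddings, LSTM/GRU and 1-D conv.

All parameters are ``Tensor`` objects collected through ``Module.parameters``;
initialization is driven by an explicit ``numpy.random.Generator`` so every
model in the package is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, sigmoid, stack, tanh


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params = []
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

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.data.shape)


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-scale, scale, size=(n_in, n_out))


class Linear(Module):
    def __init__(self, rng, n_in, n_out, bias=True):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class Embedding(Module):
    """Lookup table with a trailing UNK row (index ``n_rows``)."""

    def __init__(self, rng, n_rows, dim, init=None):
        table = rng.normal(0.0, 0.1, size=(n_rows + 1, dim))
        if init is not None:
            table[: init.shape[0]] = init
        self.table = Tensor(table, requires_grad=True)
        self.n_rows = n_rows
        self.dim = dim

    def __call__(self, idx) -> Tensor:
        idx = np.asarray(idx, dtype=np.intp)
        return self.table[idx]


class LSTM(Module):
    """Single-direction LSTM; processes a (n, d_in) or (n, batch, d_in) input."""

    def __init__(self, rng, n_in, n_hidden):
        self.Wx = Tensor(glorot(rng, n_in, 4 * n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, 4 * n_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(4 * n_hidden), requires_grad=True)
        self.n_hidden = n_hidden

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        z = x @ self.Wx + h @ self.Wh + self.b
        nh = self.n_hidden
        i = sigmoid(z[..., 0 * nh:1 * nh])
        f = sigmoid(z[..., 1 * nh:2 * nh])
        o = sigmoid(z[..., 2 * nh:3 * nh])
        g = tanh(z[..., 3 * nh:4 * nh])
        c_new = f * c + i * g
        h_new = o * tanh(c_new)
        return h_new, c_new

    def __call__(self, xs: Tensor, reverse=False):
        """Return (stacked hidden states aligned with input order, last h)."""
        n = xs.shape[0]
        tail = xs.shape[1:-1]
        h = Tensor(np.zeros(tail + (self.n_hidden,)))
        c = Tensor(np.zeros(tail + (self.n_hidden,)))
        order = range(n - 1, -1, -1) if reverse else range(n)
        outs: list = [None] * n
        for t in order:
            h, c = self.step(xs[t], h, c)
            outs[t] = h
        return stack(outs, axis=0), h


class GRU(Module):
    def __init__(self, rng, n_in, n_hidden):
        self.Wx = Tensor(glorot(rng, n_in, 3 * n_hidden), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_hidden, 3 * n_hidden), requires_grad=True)
        self.b = Tensor(np.zeros(3 * n_hidden), requires_grad=True)
        self.n_hidden = n_hidden

    def step(self, x: Tensor, h: Tensor):
        nh = self.n_hidden
        zx = x @ self.Wx + self.b
        zh = h @ self.Wh
        r = sigmoid(zx[..., 0 * nh:1 * nh] + zh[..., 0 * nh:1 * nh])
        u = sigmoid(zx[..., 1 * nh:2 * nh] + zh[..., 1 * nh:2 * nh])
        cand = tanh(zx[..., 2 * nh:3 * nh] + r * zh[..., 2 * nh:3 * nh])
        return u * h + (1.0 - u) * cand

    def __call__(self, xs: Tensor, reverse=False):
        n = xs.shape[0]
        tail = xs.shape[1:-1]
        h = Tensor(np.zeros(tail + (self.n_hidden,)))
        order = range(n - 1, -1, -1) if reverse else range(n)
        outs: list = [None] * n
        for t in order:
            h = self.step(xs[t], h)
            outs[t] = h
        return stack(outs, axis=0), h


class BiRecurrent(Module):
    """Concatenate forward and backward recurrent states per time step."""

    def __init__(self, rng, n_in, n_hidden, cell="lstm"):
        cls = LSTM if cell == "lstm" else GRU
        self.fwd = cls(rng, n_in, n_hidden)
        self.bwd = cls(rng, n_in, n_hidden)

    def __call__(self, xs: Tensor):
        hs_f, last_f = self.fwd(xs)
        hs_b, last_b = self.bwd(xs, reverse=True)
        return concat([hs_f, hs_b], axis=-1), concat([last_f, last_b], axis=-1)


class Conv1d(Module):
    """Same-padded 1-D convolution over a (n, d_in) sequence."""

    def __init__(self, rng, n_in, n_maps, width=3):
        self.W = Tensor(glorot(rng, width * n_in, n_maps), requires_grad=True)
        self.b = Tensor(np.zeros(n_maps), requires_grad=True)
        self.width = width
        self.n_in = n_in

    def __call__(self, xs: Tensor) -> Tensor:
        n = xs.shape[0]
        pad = self.width // 2
        rows = []
        zero = Tensor(np.zeros(self.n_in))
        for t in range(n):
            window = []
            for w in range(-pad, self.width - pad):
                window.append(xs[t + w] if 0 <= t + w < n else zero)
            rows.append(concat(window, axis=-1))
        return stack(rows, axis=0) @ self.W + self.b


def dropout(x: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)
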