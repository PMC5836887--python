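"""Network building blocks: dense / convolution / GRU layers and Adam.

Built on the package's own reverse-mode engine (:mod:`aemol._autodiff`).
Parameters are float32 :class:`~aemol._autodiff.Tensor` objects; every layer
exposes ``parameters()`` so optimizers and checkpointing can enumerate them.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, conv1d


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out)).astype(np.float32)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float32)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """'valid' convolution along the sequence axis; input (B, L, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        self.kernel_size = kernel_size
        fan_in = kernel_size * c_in
        self.weight = Tensor(glorot(rng, fan_in, c_out), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class GRUCell(Module):
    """Gated recurrent unit; gates fused into one matmul per input source."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.w_x = Tensor(glorot(rng, n_in, 3 * n_hidden), requires_grad=True)
        self.w_h = Tensor(glorot(rng, n_hidden, 3 * n_hidden), requires_grad=True)
        self.b_x = Tensor(np.zeros(3 * n_hidden, dtype=np.float32), requires_grad=True)
        self.b_hn = Tensor(np.zeros(n_hidden, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.n_hidden
        gx = x @ self.w_x + self.b_x
        gh = h @ self.w_h
        r = (gx[:, :H] + gh[:, :H]).sigmoid()
        u = (gx[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gx[:, 2 * H :] + r * (gh[:, 2 * H :] + self.b_hn)).tanh()
        return (1.0 - u) * n + u * h


class Adam:
    """Adaptive-moment stochastic gradient optimizer."""

    def __init__(self, params: list[Tensor], lr: float = 3.1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[i] / bc1) / (
                np.sqrt(self.v[i] / bc2) + self.eps
            )


__all__ = ["Module", "Dense", "Conv1d", "GRUCell", "Adam", "Tensor", "concat", "glorot"]
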