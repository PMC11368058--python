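"""Layer modules built on the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

_ACTS = {
    None: lambda t: t,
    "relu": lambda t: t.relu(),
    "lrelu": lambda t: t.leaky_relu(0.2),
    "elu": lambda t: t.elu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model needs {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch while loading checkpoint")
            p.data = np.ascontiguousarray(a, dtype=np.float32)


class Conv2d(Module):
    """Convolution layer, optionally with width-symmetrized kernels.

    `sym="width"` constrains the effective kernel to be left-right
    symmetric (W <- (W + flip_w W)/2), making the layer exactly
    equivariant to horizontal flips.  `sym_perm` additionally averages
    with an input-channel permutation of the flipped kernel, the
    constraint needed at the dual-path fusion convolution.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, act: str | None = None,
                 rng: np.random.Generator | None = None, gain: float = 1.0,
                 sym: str | None = None, sym_perm: np.ndarray | None = None):
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = dilation * (k - 1) // 2
        scale = gain * np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.act = act
        self.sym = sym
        self.sym_perm = None if sym_perm is None else np.asarray(sym_perm)

    def effective_weight(self) -> Tensor:
        w = self.w
        if self.sym_perm is not None:
            w = (w + w.perm_channels(self.sym_perm).flip_w()) * 0.5
        elif self.sym == "width":
            w = (w + w.flip_w()) * 0.5
        return w

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.effective_weight(), self.b, self.stride, self.padding, self.dilation)
        return _ACTS[self.act](out)


class GatedConv2d(Module):
    """Gated convolution: act(conv_f(x)) * sigmoid(conv_g(x)).

    Standard gating formulation for free-form inpainting; the feature
    path uses ELU (or tanh at the output layer), the gate is a parallel
    convolution squashed through a sigmoid so the layer can learn where
    filled-in content is valid.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, act: str = "elu",
                 rng: np.random.Generator | None = None):
        self.feat = Conv2d(cin, cout, k, stride, padding, dilation, act=act, rng=rng)
        self.gate = Conv2d(cin, cout, k, stride, padding, dilation, act=None, rng=rng, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        return self.feat(x) * self.gate(x).sigmoid()


class SNConv2d(Module):
    """Strided convolution with spectral normalization (one power
    iteration per forward; the norm is treated as a constant in the
    backward pass)."""

    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2,
                 padding: int = 1, act: str | None = "lrelu",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self._u = rng.normal(size=cout).astype(np.float32)
        self.stride, self.padding = stride, padding
        self.act = act

    def __call__(self, x: Tensor) -> Tensor:
        wmat = self.w.data.reshape(self.w.data.shape[0], -1)
        v = wmat.T @ self._u
        v /= np.linalg.norm(v) + 1e-12
        u = wmat @ v
        sigma = np.linalg.norm(u) + 1e-12
        self._u = u / sigma
        out = conv2d(x, self.w * np.float32(1.0 / sigma), self.b, self.stride, self.padding)
        return _ACTS[self.act](out)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def lr_at_epoch(lr0: float, epoch: int, halve_every: int = 5) -> float:
    """Step learning-rate schedule: halves every `halve_every` epochs."""
    return lr0 * 0.5 ** (epoch // halve_every)
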