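"""Small neural-network building blocks on top of :mod:`trajedit.autodiff`.

Parameters live in ordered dicts of named :class:`~trajedit.autodiff.Tensor`
objects so that optimizers, checkpoints and determinism tests can treat a
model as a flat collection of named arrays.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .autodiff import Tensor, concat, parameter, sigmoid, tanh

ParamDict = Dict[str, Tensor]


def fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Standard fan-in uniform initializer, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Affine:
    """y = x @ W + b, with parameters registered under ``prefix``."""

    def __init__(self, params: ParamDict, prefix: str, d_in: int, d_out: int,
                 rng: np.random.Generator):
        self.W = parameter(fan_in_uniform(rng, (d_in, d_out)))
        self.b = parameter(np.zeros(d_out))
        params[f"{prefix}.W"] = self.W
        params[f"{prefix}.b"] = self.b

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRUEncoder:
    """Single-layer gated recurrent encoder with final-state readout.

    Consumes a left-padded batch ``(B, L, d_in)`` with a per-step validity
    column ``(B, L)``; invalid (padding) steps leave the hidden state
    untouched, so the final state summarizes exactly the valid steps.
    """

    def __init__(self, params: ParamDict, prefix: str, d_in: int, d_h: int,
                 rng: np.random.Generator):
        self.d_h = d_h
        self.Wz = Affine(params, f"{prefix}.z_x", d_in, d_h, rng)
        self.Uz = Affine(params, f"{prefix}.z_h", d_h, d_h, rng)
        self.Wr = Affine(params, f"{prefix}.r_x", d_in, d_h, rng)
        self.Ur = Affine(params, f"{prefix}.r_h", d_h, d_h, rng)
        self.Wn = Affine(params, f"{prefix}.n_x", d_in, d_h, rng)
        self.Un = Affine(params, f"{prefix}.n_h", d_h, d_h, rng)

    def __call__(self, steps: list[Tensor], valid: np.ndarray) -> Tensor:
        """steps: list of L tensors (B, d_in); valid: bool (B, L)."""
        B = steps[0].shape[0]
        h = Tensor(np.zeros((B, self.d_h)))
        for t, x_t in enumerate(steps):
            z = sigmoid(self.Wz(x_t) + self.Uz(h))
            r = sigmoid(self.Wr(x_t) + self.Ur(h))
            n = tanh(self.Wn(x_t) + self.Un(h) * r)
            h_new = (Tensor(1.0) - z) * n + z * h
            v = Tensor(valid[:, t : t + 1].astype(np.float64))
            h = v * h_new + (Tensor(1.0) - v) * h
        return h


class AttentionEncoder:
    """Single-head self-attention with mean pooling over valid steps."""

    def __init__(self, params: ParamDict, prefix: str, d_in: int, d_h: int,
                 rng: np.random.Generator):
        self.d_h = d_h
        self.proj = Affine(params, f"{prefix}.in", d_in, d_h, rng)
        self.q = Affine(params, f"{prefix}.q", d_h, d_h, rng)
        self.k = Affine(params, f"{prefix}.k", d_h, d_h, rng)
        self.v = Affine(params, f"{prefix}.v", d_h, d_h, rng)
        self.out = Affine(params, f"{prefix}.out", d_h, d_h, rng)

    def __call__(self, steps: list[Tensor], valid: np.ndarray) -> Tensor:
        from .autodiff import exp, stack

        H = [self.proj(x) for x in steps]  # L tensors (B, d_h)
        L = len(H)
        Hs = stack(H, axis=1)  # (B, L, d_h)
        B = Hs.shape[0]
        Q = stack([self.q(h) for h in H], axis=1)
        K = stack([self.k(h) for h in H], axis=1)
        V = stack([self.v(h) for h in H], axis=1)
        scale = 1.0 / np.sqrt(self.d_h)
        # scores (B, L, L) via batched matmul
        scores = Q @ K.transpose(0, 2, 1) * scale
        vmask = valid.astype(np.float64)  # (B, L)
        neg = Tensor((1.0 - vmask)[:, None, :] * -1e9)
        scores = scores + neg
        m = Tensor(scores.data.max(axis=-1, keepdims=True))
        e = exp(scores - m)
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ V  # (B, L, d_h)
        ctx = self.out(ctx.reshape(B * L, self.d_h)).reshape(B, L, self.d_h)
        w = Tensor(vmask[:, :, None] / np.maximum(vmask.sum(axis=1), 1.0)[:, None, None])
        return (ctx * w).sum(axis=1)


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: ParamDict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clone_params(params: ParamDict) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in params.items()}


def load_params(params: ParamDict, blob: dict[str, np.ndarray]) -> None:
    for k, p in params.items():
        p.data = blob[k].copy()
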