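"""Minimal neural-network plumbing on top of autograd/numpy.

Parameters live in a flat ``dict[str, np.ndarray]``; forward passes are pure
functions of that dict written with ``autograd.numpy`` so gradients come from
``autograd.grad``.  This keeps the equivariant encoder/decoder free of any
framework dependency: checkpoints are plain named arrays plus a JSON config
manifest.
"""

from __future__ import annotations

import json
import os
from typing import Callable, Dict

import autograd.numpy as anp
import numpy as np

Params = Dict[str, np.ndarray]


def silu(x):
    # x * sigmoid(x); tanh form avoids exp overflow for large |x|
    return x * 0.5 * (1.0 + anp.tanh(0.5 * x))


def softplus(x):
    # numerically stable log(1 + e^x)
    return anp.logaddexp(0.0, x)


def layer_norm(x, eps=1e-6):
    """Non-affine per-row normalization; stabilizes the latent recursion."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return (x - mu) / anp.sqrt(var + eps)


def softmax(x, axis=-1):
    m = anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=axis, keepdims=True)


def init_mlp(params: Params, name: str, sizes, rng: np.random.Generator):
    """Glorot-initialized MLP weights registered under ``name``."""
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        params[f"{name}/W{i}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
        params[f"{name}/b{i}"] = np.zeros(fan_out)
    params[f"{name}/__depth"] = np.array(len(sizes) - 1)


def _depth(params: Params, name: str) -> int:
    d = params[f"{name}/__depth"]
    return int(getattr(d, "_value", d))


def mlp(params: Params, name: str, x):
    """Apply the MLP ``name``; SiLU between layers, linear output."""
    depth = _depth(params, name)
    h = x
    for i in range(depth):
        h = h @ params[f"{name}/W{i}"] + params[f"{name}/b{i}"]
        if i < depth - 1:
            h = silu(h)
    return h


def zero_mlp(params: Params, name: str):
    """Freeze an MLP to the constant zero function (for unit tests)."""
    depth = _depth(params, name)
    for i in range(depth):
        params[f"{name}/W{i}"] = np.zeros_like(params[f"{name}/W{i}"])
        params[f"{name}/b{i}"] = np.zeros_like(params[f"{name}/b{i}"])


def constant_mlp(params: Params, name: str, value: float):
    """Freeze an MLP to a constant output (zero weights, constant bias)."""
    zero_mlp(params, name)
    depth = _depth(params, name)
    params[f"{name}/b{depth - 1}"] = np.full_like(params[f"{name}/b{depth - 1}"], value)


class Adam:
    """Plain Adam over a parameter dict, with global-norm gradient clipping."""

    def __init__(self, params: Params, lr=1e-4, b1=0.9, b2=0.999, eps=1e-8,
                 clip_norm=1.0):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Params, grads: Params) -> Params:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float(np.sum(np.asarray(g) ** 2))
                for k, g in grads.items()
                if g is not None and not k.endswith("__depth")))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: (g if g is None or k.endswith("__depth") else g * scale)
                         for k, g in grads.items()}
        out = {}
        for k, p in params.items():
            g = grads.get(k)
            if g is None or k.endswith("__depth"):
                out[k] = p
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def save_checkpoint(path: str, params: Params, config: dict):
    """Named arrays (.npz) plus a JSON config manifest next to it."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    np.savez(path if path.endswith(".npz") else path + ".npz",
             **{k.replace("/", "__SL__"): v for k, v in params.items()})
    manifest = path[:-4] + ".json" if path.endswith(".npz") else path + ".json"
    with open(manifest, "w") as fh:
        json.dump(config, fh, indent=1)


def load_checkpoint(path: str):
    npz_path = path if path.endswith(".npz") else path + ".npz"
    data = np.load(npz_path)
    params = {k.replace("__SL__", "/"): data[k] for k in data.files}
    manifest = npz_path[:-4] + ".json"
    config = {}
    if os.path.exists(manifest):
        with open(manifest) as fh:
            config = json.load(fh)
    return params, config


def tree_map(fn: Callable, params: Params) -> Params:
    return {k: (v if k.endswith("__depth") else fn(v)) for k, v in params.items()}
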