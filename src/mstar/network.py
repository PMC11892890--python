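"""Mixed-scale dense (MS-D) 2D network, implemented directly on NumPy.

An MS-D network is a densely connected CNN in which every layer produces a
single feature channel (width 1) from a 3x3 *dilated* convolution over the
input and **all** previously computed channels, with the dilation cycling
through 1..10.  A final 1x1 linear layer maps every channel to the output.
The dense connectivity gives large receptive fields at a very small
parameter count, which is what makes depth-100 networks with ~45k
parameters possible.

This module provides exact trainable-parameter accounting, a deterministic
initialization, and forward/backward passes (reflection padding, ReLU)
sufficient to train stages with Adam on CPU.  Input/output normalization
constants are stored with each trained stage and applied on entry / inverted
on exit, so stages exchange data in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkSpec",
    "StageModel",
    "IdentityModel",
    "count_parameters",
    "Adam",
]

_TAPS = [(a, b) for a in range(3) for b in range(3)]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one stage network."""

    c_in: int = 1
    depth: int = 100
    c_out: int = 1
    width: int = 1  # one channel per layer; the MS-D default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.c_in < 1 or self.c_out < 1 or self.width != 1:
            raise ValueError("invalid network spec")

    def dilation(self, i: int) -> int:
        """Cyclic dilation schedule over {1..10}; layer ``i`` is 0-based."""
        return (i % 10) + 1


def count_parameters(spec: NetworkSpec) -> int:
    """Exact trainable-parameter count of an MS-D network.

    Layer ``i`` (1-based) convolves all ``c_in + i - 1`` existing channels
    with a 3x3 kernel and adds one bias; the final 1x1 layer has one weight
    per channel per output plus a bias per output.
    """
    d, c_in, c_out = spec.depth, spec.c_in, spec.c_out
    conv = sum(9 * (c_in + i - 1) + 1 for i in range(1, d + 1))
    return conv + (c_in + d) * c_out + c_out


def _init_params(spec: NetworkSpec) -> dict:
    """He-scaled convolution weights; zero-initialized final layer."""
    rng = np.random.default_rng(spec.seed)
    conv_w, conv_b = [], []
    for i in range(spec.depth):
        fan_in = 9 * (spec.c_in + i)
        conv_w.append(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(spec.c_in + i, 3, 3)).astype(
                np.float32
            )
        )
        conv_b.append(np.zeros((), dtype=np.float32))
    return {
        "conv_w": conv_w,
        "conv_b": conv_b,
        "out_w": np.zeros((spec.c_out, spec.c_in + spec.depth), dtype=np.float32),
        "out_b": np.zeros(spec.c_out, dtype=np.float32),
    }


def _params_size(params: dict) -> int:
    n = sum(w.size for w in params["conv_w"]) + sum(b.size for b in params["conv_b"])
    return n + params["out_w"].size + params["out_b"].size


def _fold_reflect_axis(g: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Adjoint of reflect-padding one axis by ``d``: fold borders inward."""
    n = g.shape[axis] - 2 * d
    core = np.take(g, np.arange(d, d + n), axis=axis).copy()
    sl = [slice(None)] * g.ndim
    for t in range(d):
        sl[axis] = d - t
        core[tuple(sl)] += np.take(g, t, axis=axis)
        sl[axis] = n - 2 - t
        core[tuple(sl)] += np.take(g, d + n + t, axis=axis)
    return core


class _Cache:
    __slots__ = ("feat", "masks", "out")


class StageModel:
    """One trained (or trainable) MS-D stage with its normalization.

    ``norm_in`` is a ``(2, c_in)`` array of per-channel (mean, std);
    ``norm_out`` is a (mean, std) pair for the single output channel.
    """

    def __init__(
        self,
        spec: NetworkSpec,
        params: dict | None = None,
        norm_in: np.ndarray | None = None,
        norm_out: tuple[float, float] = (0.0, 1.0),
    ):
        self.spec = spec
        self.params = params if params is not None else _init_params(spec)
        if _params_size(self.params) != count_parameters(spec):
            raise ValueError("parameter arrays do not match the spec")
        if norm_in is None:
            norm_in = np.array([[0.0] * spec.c_in, [1.0] * spec.c_in])
        self.norm_in = np.asarray(norm_in, dtype=np.float32)
        if self.norm_in.shape != (2, spec.c_in) or np.any(self.norm_in[1] <= 0):
            raise ValueError("norm_in must be (2, c_in) with positive stds")
        if norm_out[1] <= 0:
            raise ValueError("norm_out std must be positive")
        self.norm_out = (float(norm_out[0]), float(norm_out[1]))

    @property
    def c_in(self) -> int:
        return self.spec.c_in

    @property
    def n_parameters(self) -> int:
        return _params_size(self.params)

    # -- forward / backward ------------------------------------------------

    def _forward_core(self, xn: np.ndarray, cache: _Cache | None = None) -> np.ndarray:
        spec = self.spec
        b, c, h, w = xn.shape
        if c != spec.c_in:
            raise ValueError(f"expected {spec.c_in} input channels, got {c}")
        if h < 3 or w < 3:
            raise ValueError("spatial dims must be at least 3")
        feat = np.empty((b, spec.c_in + spec.depth, h, w), dtype=np.float32)
        feat[:, : spec.c_in] = xn
        masks = [] if cache is not None else None
        for i in range(spec.depth):
            d = spec.dilation(i)
            c_i = spec.c_in + i
            xp = np.pad(
                feat[:, :c_i], ((0, 0), (0, 0), (d, d), (d, d)), mode="reflect"
            )
            z = np.full((b, h, w), self.params["conv_b"][i], dtype=np.float32)
            wmat = self.params["conv_w"][i]
            for a, bb in _TAPS:
                view = xp[:, :, a * d : a * d + h, bb * d : bb * d + w]
                z += np.tensordot(view, wmat[:, a, bb], axes=([1], [0]))
            if masks is not None:
                masks.append(z > 0)
            feat[:, c_i] = np.maximum(z, 0.0)
        out = (
            np.einsum("oc,bchw->bohw", self.params["out_w"], feat)
            + self.params["out_b"][None, :, None, None]
        )
        if cache is not None:
            cache.feat, cache.masks, cache.out = feat, masks, out
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Apply the stage to a batch (B, c_in, H, W) in physical units."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"expected (B, {self.spec.c_in}, H, W) input channels, "
                f"got shape {x.shape}"
            )
        xn = (x - self.norm_in[0][None, :, None, None]) / self.norm_in[1][
            None, :, None, None
        ]
        y = self._forward_core(xn)
        return y * np.float32(self.norm_out[1]) + np.float32(self.norm_out[0])

    def _backward_core(self, cache: _Cache, g_out: np.ndarray) -> dict:
        """Gradients of the cached forward pass w.r.t. all parameters."""
        spec = self.spec
        feat, masks = cache.feat, cache.masks
        b, _, h, w = feat.shape
        grads = {
            "conv_w": [np.zeros_like(wm) for wm in self.params["conv_w"]],
            "conv_b": [np.zeros((), dtype=np.float32) for _ in range(spec.depth)],
            "out_w": np.einsum("bohw,bchw->oc", g_out, feat).astype(np.float32),
            "out_b": g_out.sum(axis=(0, 2, 3)).astype(np.float32),
        }
        g_feat = np.einsum("oc,bohw->bchw", self.params["out_w"], g_out).astype(
            np.float32
        )
        for i in reversed(range(spec.depth)):
            d = spec.dilation(i)
            c_i = spec.c_in + i
            gz = g_feat[:, c_i] * masks[i]
            grads["conv_b"][i] = gz.sum().astype(np.float32)
            xp = np.pad(
                feat[:, :c_i], ((0, 0), (0, 0), (d, d), (d, d)), mode="reflect"
            )
            gxp = np.zeros_like(xp)
            wmat = self.params["conv_w"][i]
            for a, bb in _TAPS:
                view = xp[:, :, a * d : a * d + h, bb * d : bb * d + w]
                grads["conv_w"][i][:, a, bb] = np.einsum("bchw,bhw->c", view, gz)
                gxp[:, :, a * d : a * d + h, bb * d : bb * d + w] += (
                    wmat[:, a, bb][None, :, None, None] * gz[:, None]
                )
            folded = _fold_reflect_axis(_fold_reflect_axis(gxp, d, 2), d, 3)
            g_feat[:, :c_i] += folded
        return grads

    def training_step(
        self, x: np.ndarray, target: np.ndarray, optimizer: "Adam"
    ) -> float:
        """One MSE gradient step on a batch in physical units; returns loss."""
        x = np.asarray(x, dtype=np.float32)
        target = np.asarray(target, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.spec.c_in:
            raise ValueError(
                f"expected (B, {self.spec.c_in}, H, W) input channels, "
                f"got shape {x.shape}"
            )
        xn = (x - self.norm_in[0][None, :, None, None]) / self.norm_in[1][
            None, :, None, None
        ]
        cache = _Cache()
        yn = self._forward_core(xn, cache)
        mu, sd = self.norm_out
        y = yn * np.float32(sd) + np.float32(mu)
        resid = y - target
        loss = float(np.mean(resid.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError("training loss became non-finite")
        g_out = (2.0 / resid.size) * resid * np.float32(sd)
        grads = self._backward_core(cache, g_out.astype(np.float32))
        optimizer.step(self.params, grads)
        return loss

    def loss(self, x: np.ndarray, target: np.ndarray) -> float:
        """MSE of the stage output against a target, both in physical units."""
        y = self.predict(x)
        return float(np.mean((y.astype(np.float64) - np.asarray(target)) ** 2))

    # -- persistence -------------------------------------------------------

    def copy_params(self) -> dict:
        return {
            "conv_w": [w.copy() for w in self.params["conv_w"]],
            "conv_b": [b.copy() for b in self.params["conv_b"]],
            "out_w": self.params["out_w"].copy(),
            "out_b": self.params["out_b"].copy(),
        }

    def set_params(self, params: dict) -> None:
        if _params_size(params) != count_parameters(self.spec):
            raise ValueError("parameter arrays do not match the spec")
        self.params = params

    def save(self, path) -> None:
        arrays = {
            "out_w": self.params["out_w"],
            "out_b": self.params["out_b"],
            "norm_in": self.norm_in,
            "norm_out": np.array(self.norm_out),
            "spec": np.array(
                [self.spec.c_in, self.spec.depth, self.spec.c_out, self.spec.seed]
            ),
            "format_version": np.array([1]),
        }
        for i, (w, b) in enumerate(zip(self.params["conv_w"], self.params["conv_b"])):
            arrays[f"conv_w_{i}"] = w
            arrays[f"conv_b_{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "StageModel":
        with np.load(path) as zf:
            c_in, depth, c_out, seed = (int(v) for v in zf["spec"])
            spec = NetworkSpec(c_in=c_in, depth=depth, c_out=c_out, seed=seed)
            params = {
                "conv_w": [zf[f"conv_w_{i}"] for i in range(depth)],
                "conv_b": [zf[f"conv_b_{i}"] for i in range(depth)],
                "out_w": zf["out_w"],
                "out_b": zf["out_b"],
            }
            return cls(spec, params, zf["norm_in"], tuple(zf["norm_out"]))


class IdentityModel:
    """Stand-in stage that returns its last input channel unchanged.

    Used to verify the pass-through contracts of the multi-stage chain:
    with identity stages the chain must reduce to the classical no-op
    pipeline.
    """

    def __init__(self, c_in: int = 1):
        self.c_in = c_in

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {x.shape[1]}")
        return x[:, -1:].copy()


class Adam:
    """Adam optimizer over the nested parameter dict of a stage."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict | None = None
        self._v: dict | None = None

    def _zeros_like(self, params: dict) -> dict:
        return {
            "conv_w": [np.zeros_like(w) for w in params["conv_w"]],
            "conv_b": [np.zeros_like(b) for b in params["conv_b"]],
            "out_w": np.zeros_like(params["out_w"]),
            "out_b": np.zeros_like(params["out_b"]),
        }

    def step(self, params: dict, grads: dict) -> None:
        if self._m is None:
            self._m = self._zeros_like(params)
            self._v = self._zeros_like(params)
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t

        def upd(p, g, m, v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                p.dtype, copy=False
            )

        for i in range(len(params["conv_w"])):
            upd(params["conv_w"][i], grads["conv_w"][i],
                self._m["conv_w"][i], self._v["conv_w"][i])
            # scalar biases: operate in-place via 0-d arrays
            upd(params["conv_b"][i].reshape(()), grads["conv_b"][i],
                self._m["conv_b"][i].reshape(()), self._v["conv_b"][i].reshape(()))
        upd(params["out_w"], grads["out_w"], self._m["out_w"], self._v["out_w"])
        upd(params["out_b"], grads["out_b"], self._m["out_b"], self._v["out_b"])
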