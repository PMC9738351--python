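"""Minimal vectorized neural-network engine (NumPy).

Implements exactly the layer set the classifier architecture needs —
row-wise 2-D convolution and max pooling with kernel height 1 (the EEG
channel dimension is never mixed), dense layers, inverted dropout and a
softmax/cross-entropy head — plus the Adam optimizer.  Forward and
backward passes are explicit; convolutions are lowered to matrix products
via an im2col view, so all heavy arithmetic is BLAS.

Tensors are NHWC: (batch, channels=19, samples, planes), float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1xN",
    "MaxPool1xN",
    "Flatten",
    "Dense",
    "Dropout",
    "Network",
    "Adam",
    "softmax",
    "cross_entropy",
    "conv_output_width",
    "pad_amounts",
]


def conv_output_width(w: int, k: int, stride: int, padding: str) -> int:
    """Output width of a width-wise conv/pool window."""
    if padding == "same":
        return -(-w // stride)  # ceil
    if padding == "valid":
        if w < k:
            raise ValueError(f"window {k} wider than input {w} with 'valid' padding")
        return (w - k) // stride + 1
    raise ValueError(f"unknown padding {padding!r}")


def pad_amounts(w: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    """(left, right) zero padding; TensorFlow 'same' convention."""
    if padding == "valid":
        return 0, 0
    out = conv_output_width(w, k, stride, padding)
    total = max((out - 1) * stride + k - w, 0)
    return total // 2, total - total // 2


def _tap(x: np.ndarray, j: int, stride: int, wout: int) -> np.ndarray:
    """The j-th kernel tap across all output positions: x[..., j::stride, :]."""
    return x[:, :, j : j + stride * (wout - 1) + 1 : stride, :]


def _gather_windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Materialize sliding windows along the width axis: (B, H, Wout, k, C)."""
    b, h, w, c = x.shape
    wout = (w - k) // stride + 1
    cols = np.empty((b, h, wout, k, c), dtype=x.dtype)
    for j in range(k):
        cols[:, :, :, j, :] = _tap(x, j, stride, wout)
    return cols


class Layer:
    """Base layer; parameterless layers override only forward/backward."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1xN(Layer):
    """2-D convolution with a 1 x k kernel: a 1-D conv applied per channel row."""

    def __init__(self, k: int, stride: int, padding: str, in_planes: int,
                 filters: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding
        self.activation = activation
        fan_in = k * in_planes
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU layers
        self.params["W"] = (rng.standard_normal((fan_in, filters)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(filters, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pl, pr = pad_amounts(x.shape[2], self.k, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0))) if pl or pr else x
        cols = _gather_windows(xp, self.k, self.stride)  # (B,H,Wout,k,C)
        b, h, wout = cols.shape[:3]
        self._cols = cols.reshape(b * h * wout, -1)
        self._in_shape, self._pads = x.shape, (pl, pr)
        z = self._cols @ self.params["W"] + self.params["b"]
        z = z.reshape(b, h, wout, -1)
        if self.activation == "relu":
            self._mask = z > 0
            z *= self._mask
        return z

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        if self.activation == "relu":
            grad = grad * self._mask
        b, h, wout, f = grad.shape
        g2 = grad.reshape(-1, f)
        self.grads["W"] = self._cols.T @ g2
        self.grads["b"] = g2.sum(axis=0)
        if not need_input_grad:
            return grad
        pl, pr = self._pads
        bs, hs, w, c = self._in_shape
        gpad = np.zeros((bs, hs, w + pl + pr, c), dtype=grad.dtype)
        gw = (g2 @ self.params["W"].T).reshape(b, h, wout, self.k, c)
        for j in range(self.k):  # taps at fixed j hit distinct positions
            _tap(gpad, j, self.stride, wout)[...] += gw[:, :, :, j, :]
        return gpad[:, :, pl : pl + w, :]


class MaxPool1xN(Layer):
    """Max pooling with a 1 x k window along the sample axis."""

    def __init__(self, k: int, stride: int, padding: str):
        super().__init__()
        self.k, self.stride, self.padding = k, stride, padding

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pl, pr = pad_amounts(x.shape[2], self.k, self.stride, self.padding)
        if pl or pr:
            xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)),
                        constant_values=-np.inf)
        else:
            xp = x
        self._in_shape, self._pads, self._padded_w = x.shape, (pl, pr), xp.shape[2]
        b, h, wp, c = xp.shape
        wout = (wp - self.k) // self.stride + 1
        best = _tap(xp, 0, self.stride, wout).copy()
        if not train:  # inference: no argmax bookkeeping needed
            for j in range(1, self.k):
                np.maximum(best, _tap(xp, j, self.stride, wout), out=best)
            return best
        amax = np.zeros(best.shape, dtype=np.int8)
        for j in range(1, self.k):  # first occurrence of the max wins
            cand = _tap(xp, j, self.stride, wout)
            sel = cand > best
            np.copyto(best, cand, where=sel)
            amax[sel] = j
        self._amax = amax
        return best

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        pl, pr = self._pads
        b, h, w, c = self._in_shape
        wout = grad.shape[2]
        if self.stride == self.k and self._padded_w % self.k == 0:
            win = np.zeros((b, h, wout, self.k, c), dtype=grad.dtype)
            np.put_along_axis(
                win, self._amax[:, :, :, None, :].astype(np.intp),
                grad[:, :, :, None, :], axis=3,
            )
            gpad = win.reshape(b, h, self._padded_w, c)
            return gpad[:, :, pl : pl + w, :]
        gpad = np.zeros((b, h, self._padded_w, c), dtype=grad.dtype)
        for j in range(self.k):
            _tap(gpad, j, self.stride, wout)[...] += np.where(
                self._amax == j, grad, 0.0
            )
        return gpad[:, :, pl : pl + w, :]


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, units: int, activation: str, rng: np.random.Generator):
        super().__init__()
        self.activation = activation
        if activation == "relu":
            scale = np.sqrt(2.0 / n_in)
        else:  # linear / softmax head: Glorot
            scale = np.sqrt(1.0 / n_in)
        self.params["W"] = (rng.standard_normal((n_in, units)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(units, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            self._mask = z > 0
            z = np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        if self.activation == "relu":
            grad = np.where(self._mask, grad, 0.0)
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T if need_input_grad else grad


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 < rate < 1:
            raise ValueError(f"dropout rate must be in (0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.sum(onehot * np.log(probs + eps), axis=-1)))


class Network:
    """An ordered stack of layers ending in softmax logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return softmax(x)

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        # combined softmax + cross-entropy gradient
        grad = (probs - onehot).astype(np.float32) / probs.shape[0]
        for i in range(len(self.layers) - 1, -1, -1):
            grad = self.layers[i].backward(grad, need_input_grad=i > 0)

    def parameter_layers(self) -> list[Layer]:
        return [l for l in self.layers if l.params]

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers)

    def state(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for layer, st in zip(self.layers, state):
            for k, v in st.items():
                layer.params[k] = v.copy()


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, net: Network, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in net.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[i][k]
                v = self.v[i][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
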