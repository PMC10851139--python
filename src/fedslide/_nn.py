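"""Minimal numpy neural-network core used by the patch classifiers.

Implements exactly the pieces the slide classifiers need: 2-D convolution
(im2col), batch normalization, ReLU, max/global-average pooling, a linear
head, residual blocks, softmax cross-entropy and SGD with momentum.  All
arithmetic is float32 numpy; with a fixed seed and a fixed thread count the
whole training loop is bitwise reproducible, which the federation identity
checks rely on.

Layout is NCHW throughout.  Parameters live inside layer objects and are
exported/imported as flat ``{name: array}`` state dicts so that weight
containers can be averaged across sites without knowing the architecture.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Net",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "BasicBlock",
    "SGD",
    "softmax",
    "softmax_cross_entropy",
]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Return (cols, out_h, out_w); cols has shape (N, C*k*k, out_h*out_w)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    out_h = (hp - k) // stride + 1
    out_w = (wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, k, k, out_h, out_w),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = windows.reshape(n, c * k * k, out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Scatter-add column gradients back to input layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    out_h = (hp - k) // stride + 1
    out_w = (wp - k) // stride + 1
    dcols = dcols.reshape(n, c, k, k, out_h, out_w)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for i in range(k):
        i_max = i + stride * out_h
        for j in range(k):
            j_max = j + stride * out_w
            dx[:, :, i:i_max:stride, j:j_max:stride] += dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Layer:
    """Base layer: forward/backward plus named parameter export."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def named_arrays(self):
        """Yield (name, array, is_trainable)."""
        return
        yield  # pragma: no cover

    def grads(self):
        return {}

    def load(self, arrays: dict) -> None:
        for name, arr, _ in self.named_arrays():
            np.copyto(arr, arrays[name])


class Conv2d(Layer):
    def __init__(self, c_in, c_out, k=3, stride=1, pad=1, rng=None):
        self.k, self.stride, self.pad = k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k * k))
        rng = rng or np.random.default_rng(0)
        self.weight = (rng.standard_normal((c_out, c_in, k, k)) * scale).astype(np.float32)
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, x, train):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.weight.reshape(self.weight.shape[0], -1)
        out = np.einsum("fc,ncl->nfl", w2, cols, optimize=True)
        out += self.bias[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, grad):
        x_shape, cols = self._cache
        n, f = grad.shape[0], grad.shape[1]
        g2 = grad.reshape(n, f, -1)
        self.dweight[...] = np.einsum("nfl,ncl->fc", g2, cols, optimize=True).reshape(
            self.weight.shape
        )
        self.dbias[...] = g2.sum(axis=(0, 2))
        w2 = self.weight.reshape(f, -1)
        dcols = np.einsum("fc,nfl->ncl", w2, g2, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def named_arrays(self):
        yield "weight", self.weight, True
        yield "bias", self.bias, True

    def grads(self):
        return {"weight": self.dweight, "bias": self.dbias}


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.weight = np.ones(c, dtype=np.float32)
        self.bias = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.weight[None, :, None, None] * xhat + self.bias[None, :, None, None]

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        self.dweight[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbias[...] = grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.weight[None, :, None, None]
        if not train:
            return gxhat * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * gxhat - t1 - xhat * t2)

    def named_arrays(self):
        yield "weight", self.weight, True
        yield "bias", self.bias, True
        yield "running_mean", self.running_mean, False
        yield "running_var", self.running_var, False

    def grads(self):
        return {"weight": self.dweight, "bias": self.dbias}


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2d(Layer):
    def __init__(self, k=2, stride=None, pad=0):
        self.k = k
        self.stride = stride or k
        self.pad = pad

    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        if self.pad:
            xr = np.pad(
                xr,
                ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        cols, oh, ow = _im2col(xr, self.k, self.stride, 0)
        cols = cols.reshape(n * c, self.k * self.k, oh * ow)
        self._arg = cols.argmax(axis=1)
        out = np.take_along_axis(cols, self._arg[:, None, :], axis=1)[:, 0, :]
        self._in_shape = (n, c, h, w)
        self._out_hw = (oh, ow)
        return out.reshape(n, c, oh, ow)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        oh, ow = self._out_hw
        g = grad.reshape(n * c, oh * ow)
        dcols = np.zeros((n * c, self.k * self.k, oh * ow), dtype=grad.dtype)
        np.put_along_axis(dcols, self._arg[:, None, :], g[:, None, :], axis=1)
        dx = _col2im(
            dcols.reshape(n * c, 1 * self.k * self.k, oh * ow),
            (n * c, 1, h, w),
            self.k,
            self.stride,
            self.pad,
        )
        return dx.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / self._hw


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in)
        self.weight = (rng.standard_normal((d_out, d_in)) * scale).astype(np.float32)
        self.bias = np.zeros(d_out, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, grad):
        self.dweight[...] = grad.T @ self._x
        self.dbias[...] = grad.sum(axis=0)
        return grad @ self.weight

    def named_arrays(self):
        yield "weight", self.weight, True
        yield "bias", self.bias, True

    def grads(self):
        return {"weight": self.dweight, "bias": self.dbias}


class BasicBlock(Layer):
    """Two 3x3 conv+BN with identity (or 1x1-projected) skip, post-add ReLU."""

    def __init__(self, c_in, c_out, stride=1, rng=None):
        self.conv1 = Conv2d(c_in, c_out, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = Conv2d(c_in, c_out, 1, stride, 0, rng)
            self.down_bn = BatchNorm2d(c_out)
        else:
            self.down_conv = self.down_bn = None
        self.relu_out = ReLU()

    def _children(self):
        kids = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.down_conv is not None:
            kids += [("down_conv", self.down_conv), ("down_bn", self.down_bn)]
        return kids

    def forward(self, x, train):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        if self.down_conv is not None:
            skip = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            skip = x
        return self.relu_out.forward(out + skip, train)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(grad))))
        )
        if self.down_conv is not None:
            d_skip = self.down_conv.backward(self.down_bn.backward(grad))
        else:
            d_skip = grad
        return d_main + d_skip

    def named_arrays(self):
        for prefix, child in self._children():
            for name, arr, trainable in child.named_arrays():
                yield f"{prefix}.{name}", arr, trainable

    def grads(self):
        out = {}
        for prefix, child in self._children():
            for name, g in child.grads().items():
                out[f"{prefix}.{name}"] = g
        return out

    def load(self, arrays):
        for prefix, child in self._children():
            child.load({n: arrays[f"{prefix}.{n}"] for n, _, _ in child.named_arrays()})


class Net:
    """A plain sequence of layers with flat, index-prefixed parameter names."""

    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def state_dict(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr, _ in layer.named_arrays():
                out[f"{i}.{name}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            sub = {
                name: state[f"{i}.{name}"] for name, _, _ in layer.named_arrays()
            }
            layer.load(sub)

    def trainable(self):
        """Yield (name, array, grad) for every trainable parameter."""
        for i, layer in enumerate(self.layers):
            grads = layer.grads()
            for name, arr, trainable in layer.named_arrays():
                if trainable:
                    yield f"{i}.{name}", arr, grads[name]

    def n_params(self) -> int:
        return sum(arr.size for _, arr, _ in self._all_arrays())

    def _all_arrays(self):
        for i, layer in enumerate(self.layers):
            for name, arr, trainable in layer.named_arrays():
                yield f"{i}.{name}", arr, trainable


class SGD:
    """SGD with classical momentum; velocity persists across calls."""

    def __init__(self, net: Net, momentum: float = 0.9):
        self.net = net
        self.momentum = momentum
        self.velocity = {name: np.zeros_like(arr) for name, arr, _ in net.trainable()}

    def step(self, lr: float) -> None:
        for name, arr, grad in self.net.trainable():
            v = self.velocity[name]
            v *= self.momentum
            v -= lr * grad
            arr += v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and gradient w.r.t. logits for integer targets."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)
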