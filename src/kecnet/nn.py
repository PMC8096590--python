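"""Minimal 1-D CNN building blocks with hand-written reverse-mode gradients.

Everything KecNet needs and nothing more: same-padding 1-D convolution
(direct shift-matmul for short kernels, FFT for the long sinc kernels),
ReLU, max-pooling, inverted dropout, batch normalization over channels,
global average pooling, dense layers, softmax cross-entropy, and Adam.

The sinc convolution layer is the interesting one: its kernels are
materialized from two cutoff frequencies per filter, and the backward pass
chains the kernel-tap gradient through the analytic derivative

    d/df [ 2*f*sinc(2*pi*f*n) ] = 2*cos(2*pi*f*n)

(also valid at n = 0), then through the |.|/floor/clip reparameterization
onto the unconstrained raw parameters.  Only 2F values are trainable
regardless of kernel length.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import fft as sfft

from .sinc import SincParams, WindowSpec, constrain_cutoffs, window_values


class Layer:
    """Base: subclasses fill ``params``/``grads`` dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class SincConv1d(Layer):
    """Bank of learnable windowed-sinc bandpass filters, stride 1, same pad.

    No bias and no gain: the trainable state is exactly ``raw_low`` and
    ``raw_band`` (F values each).  Always the first layer, so no input
    gradient is computed.
    """

    def __init__(self, sinc_params: SincParams, window: WindowSpec = WindowSpec(),
                 dtype=np.float32) -> None:
        super().__init__()
        self.sp = sinc_params
        self.window = window
        self.dtype = dtype
        self.params = {
            "raw_low": sinc_params.raw_low.astype(np.float64),
            "raw_band": sinc_params.raw_band.astype(np.float64),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        L = self.sp.kernel_length
        self._half = (L - 1) // 2
        self._offsets = np.arange(L, dtype=np.float64) - self._half
        self._window_vals = window_values(L, window)

    def current_cutoffs(self) -> np.ndarray:
        """(F, 2) constrained (f_L, f_H) pairs in Hz for the live params."""
        fs, mb = self.sp.sample_rate, self.sp.min_band
        return np.asarray(
            [
                constrain_cutoffs(lo, bw, fs, mb)
                for lo, bw in zip(self.params["raw_low"], self.params["raw_band"])
            ]
        )

    def materialize_kernels(self) -> np.ndarray:
        """(F, L) float64 kernels for the current constrained cutoffs."""
        fs = self.sp.sample_rate
        cut = self.current_cutoffs()
        n = self._offsets
        fl = cut[:, 0:1] / fs
        fh = cut[:, 1:2] / fs

        def lowpass(f_hat: np.ndarray) -> np.ndarray:
            x = 2.0 * np.pi * f_hat * n
            out = np.empty_like(x)
            nz = n != 0
            out[:, nz] = 2.0 * f_hat * np.sin(x[:, nz]) / x[:, nz]
            out[:, ~nz] = 2.0 * f_hat[:, 0:1]
            return out

        return (lowpass(fh) - lowpass(fl)) * self._window_vals

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (B, 1, T) -> (B, F, T) via one shared FFT of the input
        T = x.shape[2]
        L, c = self.sp.kernel_length, self._half
        N = sfft.next_fast_len(T + L - 1)
        self._T, self._N = T, N
        self._xf = sfft.rfft(x[:, 0, :].astype(self.dtype), n=N)  # (B, Nf)
        self._cut = self.current_cutoffs()
        kernels = self.materialize_kernels().astype(self.dtype)
        kf = sfft.rfft(kernels, n=N)  # (F, Nf)
        y = sfft.irfft(self._xf[:, None, :] * kf[None, :, :], n=N)
        return y[:, :, c:c + T].astype(self.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> None:
        # Kernel-tap gradient dK[f,l] = sum_{b,t} dy[b,f,t] x[b,t+c-l] via
        # frequency-domain correlation (the padded FFT length N >= T+L-1
        # makes the circular correlation exact), then projection onto the
        # analytic cutoff derivative d kernel / d f_hat = w(n) 2cos(2pi f n).
        T, N, c = self._T, self._N, self._half
        L = self.sp.kernel_length
        fs, mb = self.sp.sample_rate, self.sp.min_band
        nyq = fs / 2.0
        dyf = sfft.rfft(np.ascontiguousarray(dy), n=N)  # (B, F, Nf)
        corr_f = np.einsum("bfk,bk->fk", dyf.conj(), self._xf)
        corr = sfft.irfft(corr_f, n=N)  # corr[f, m] = sum_t dy[t] x[t+m]
        dK = corr[:, (c - np.arange(L)) % N].astype(np.float64)

        n = self._offsets
        w = self._window_vals
        fl_hat = self._cut[:, 0:1] / fs
        fh_hat = self._cut[:, 1:2] / fs
        d_fh = (dK * (w * 2.0 * np.cos(2.0 * np.pi * fh_hat * n))).sum(axis=1) / fs
        d_fl = (dK * (w * -2.0 * np.cos(2.0 * np.pi * fl_hat * n))).sum(axis=1) / fs

        raw_low = self.params["raw_low"]
        raw_band = self.params["raw_band"]
        band = np.maximum(np.abs(raw_band), mb)
        low = np.minimum(np.abs(raw_low), nyq - mb)
        fh_unclipped = (low + band) < nyq
        band_active = np.abs(raw_band) > mb
        low_active = np.abs(raw_low) < (nyq - mb)

        d_low_total = d_fl + d_fh * fh_unclipped
        self.grads["raw_low"] = d_low_total * np.sign(raw_low) * low_active
        self.grads["raw_band"] = d_fh * fh_unclipped * np.sign(raw_band) * band_active
        return None  # first layer: no input gradient needed

    @property
    def n_params(self) -> int:
        return 2 * self.sp.n_filters


class Conv1dSame(Layer):
    """Standard 1-D cross-correlation, stride 1, same padding.

    Even kernel lengths pad one sample more on the right, matching the
    usual "same" convention.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 bias: bool = True, first_layer: bool = False,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * k))  # He init for ReLU nets
        self.params = {"W": (rng.standard_normal((c_out, c_in, k)) * scale).astype(dtype)}
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.k, self.c = k, (k - 1) // 2
        self.first_layer = first_layer

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        if self.first_layer and C == 1 and self.k >= 16:
            return self._forward_fft(x)
        xp = np.pad(x, ((0, 0), (0, 0), (self.c, self.k - 1 - self.c)))
        self._xp, self._T = xp, T
        W = self.params["W"]
        y = np.zeros((B, W.shape[0], T), dtype=x.dtype)
        for k in range(self.k):
            y += np.einsum("oc,bct->bot", W[:, :, k], xp[:, :, k:k + T], optimize=True)
        if "b" in self.params:
            y += self.params["b"][None, :, None]
        return y

    def _forward_fft(self, x: np.ndarray) -> np.ndarray:
        # long single-channel first-layer kernels: FFT cross-correlation
        # y[t] = sum_l W[l] x[t + l - c]
        B, _, T = x.shape
        N = sfft.next_fast_len(T + self.k - 1)
        self._T, self._N = T, N
        self._xf = sfft.rfft(x[:, 0, :], n=N)  # (B, Nf)
        wf = sfft.rfft(self.params["W"][:, 0, ::-1], n=N)  # reversed: correlate
        full = sfft.irfft(self._xf[:, None, :] * wf[None, :, :], n=N)
        # full[m] = sum_l x[m - (k-1) + l + ...]; align so tap c sits at t
        start = self.k - 1 - self.c
        y = full[:, :, start:start + T]
        if "b" in self.params:
            y = y + self.params["b"][None, :, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> Optional[np.ndarray]:
        if self.first_layer and hasattr(self, "_xf") and self.k >= 16:
            return self._backward_fft(dy)
        xp, T = self._xp, self._T
        W = self.params["W"]
        dW = np.empty_like(W)
        for k in range(self.k):
            dW[:, :, k] = np.einsum("bot,bct->oc", dy, xp[:, :, k:k + T], optimize=True)
        self.grads["W"] = dW
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2))
        if self.first_layer:
            return None
        dxp = np.zeros_like(xp)
        for k in range(self.k):
            dxp[:, :, k:k + T] += np.einsum("oc,bot->bct", W[:, :, k], dy, optimize=True)
        return dxp[:, :, self.c:self.c + T]

    def _backward_fft(self, dy: np.ndarray) -> None:
        # dW[o,l] = sum_{b,t} dy[b,o,t] x[b, t + l - c]: frequency-domain
        # correlation, exact because N >= T + k - 1
        T, N = self._T, self._N
        dyf = sfft.rfft(np.ascontiguousarray(dy), n=N)  # (B, Cout, Nf)
        corr_f = np.einsum("bok,bk->ok", dyf.conj(), self._xf)
        corr = sfft.irfft(corr_f, n=N)  # corr[o, m] = sum_t dy[t] x[t+m]
        idx = (np.arange(self.k) - self.c) % N
        self.grads["W"] = corr[:, idx][:, None, :].astype(self.params["W"].dtype)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2))
        return None


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Size-2 stride-2 max pooling; input length must be even."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        B, C, T = x.shape
        if T % 2:
            raise ValueError(f"pooling needs even length, got {T}")
        a, b = x[:, :, 0::2], x[:, :, 1::2]
        self._take_b = b > a  # ties go to the earlier sample
        self._shape = x.shape
        return np.where(self._take_b, b, a)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dy.dtype)
        take = self._take_b
        dx[:, :, 0::2] = np.where(take, 0, dy)
        dx[:, :, 1::2] = np.where(take, dy, 0)
        return dx


class Dropout(Layer):
    """Inverted dropout; draws masks from a shared training RNG."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: Optional[np.random.Generator] = None  # set by the trainer

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = 1.0 - self.rate
        draw = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (draw < keep).astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, time).

    Inference statistics come from an explicit recalibration pass
    (``start_collect``/``finish_collect``) that aggregates exact population
    moments over training data — with few optimizer steps per epoch the
    usual momentum-smoothed running estimates lag badly behind the weights.
    A momentum-based running update is kept as a fallback between passes.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self.collecting = False

    def start_collect(self) -> None:
        self.collecting = True
        self._sum = np.zeros_like(self.running_mean)
        self._sumsq = np.zeros_like(self.running_mean)
        self._count = 0

    def finish_collect(self) -> None:
        self.collecting = False
        if self._count:
            mean = self._sum / self._count
            self.running_mean = mean
            self.running_var = np.maximum(self._sumsq / self._count - mean**2, 0.0)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training or self.collecting:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            if self.collecting:
                n = x.shape[0] * x.shape[2]
                self._sum += np.asarray(mean, dtype=np.float64) * n
                self._sumsq += (np.asarray(var, dtype=np.float64)
                                + np.asarray(mean, dtype=np.float64) ** 2) * n
                self._count += n
            else:
                self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
                self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        mean = mean.astype(x.dtype)
        ivar = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean[None, :, None]) * ivar[None, :, None]
        self._cache = (xhat, ivar, x.shape[0] * x.shape[2])
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar, N = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2)).astype(dy.dtype)
        self.grads["beta"] = dy.sum(axis=(0, 2)).astype(dy.dtype)
        g = self.params["gamma"][None, :, None]
        dxhat = dy * g
        sum_dxhat = dxhat.sum(axis=(0, 2), keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (ivar[None, :, None] / N) * (N * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)
        return dx.astype(dy.dtype)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._T, axis=2) / self._T


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params = {
            "W": (rng.standard_normal((d_in, d_out)) * scale).astype(dtype),
            "b": np.zeros(d_out, dtype=dtype),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_with_grad(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = float(-(onehot * np.log(probs + eps)).sum() / logits.shape[0])
    grad = ((probs - onehot) / logits.shape[0]).astype(logits.dtype)
    return loss, grad, probs


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, lr: float = 3e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, dict[str, np.ndarray]] = {}
        self.v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        for i, layer in enumerate(layers):
            if not layer.params:
                continue
            m = self.m.setdefault(i, {n: np.zeros_like(p, dtype=np.float64)
                                      for n, p in layer.params.items()})
            v = self.v.setdefault(i, {n: np.zeros_like(p, dtype=np.float64)
                                      for n, p in layer.params.items()})
            for name, p in layer.params.items():
                g = layer.grads[name].astype(np.float64)
                m[name] = self.b1 * m[name] + (1 - self.b1) * g
                v[name] = self.b2 * v[name] + (1 - self.b2) * g * g
                mhat = m[name] / (1 - self.b1 ** self.t)
                vhat = v[name] / (1 - self.b2 ** self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
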