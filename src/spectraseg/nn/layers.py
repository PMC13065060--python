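"""Minimal numpy layers with hand-written reverse-mode gradients.

All layers operate on 5-D feature tensors (B, C, F, H, W) where F is the
energy-bin axis.  Each layer caches what its backward pass needs during
``forward`` and releases it after ``backward``; gradient correctness is
guarded by finite-difference tests.

Initialization is derived from a (seed, layer-name) pair so that layers
shared between architecture variants (e.g. the convolutions of ``sp`` and
``e_sp``) receive *identical* initial weights — this makes ablation deltas
attributable to the extra modules rather than to initialization noise.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "Param", "Module", "Conv3d", "InstanceNorm3d", "LeakyReLU",
    "MaxPool1x2x2", "ConvTranspose1x2x2", "SpectralSE", "EnergyFiLM",
    "FourierGate", "SpectralFusionHead", "layer_rng",
]


def layer_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-layer init stream keyed by seed and layer name."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


class Param:
    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base: subclasses implement forward(x) and backward(dy)."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def astype(self, dtype) -> "Module":
        for p in self.params():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        return self


class Conv3d(Module):
    """3x3x3 same-padded convolution over (F, H, W), stride 1.

    Computed as an accumulation of 27 shifted-slab matrix products (one
    small gemm per kernel offset), which avoids materializing the 27x
    im2col buffer and is markedly faster at these channel widths.
    """

    KS = 3

    def __init__(self, cin: int, cout: int, seed: int, name: str,
                 leaky_slope: float = 0.01):
        rng = layer_rng(seed, name)
        fan_in = cin * self.KS ** 3
        gain = np.sqrt(2.0 / (1.0 + leaky_slope ** 2))
        std = gain / np.sqrt(fan_in)
        self.w = Param(f"{name}.w",
                       rng.normal(0.0, std, size=(cout, cin, 3, 3, 3)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self.cin, self.cout = cin, cout
        self._cache = None

    #: inputs with B*D*H*W at or below this use the one-gemm im2col path
    #: (python-call overhead dominates there); larger inputs use the
    #: memory-lean shifted-slab path.
    IM2COL_MAX_VOXELS = 4096

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        if B * D * H * W <= self.IM2COL_MAX_VOXELS:
            # column matrix (27*C, N) with kernel offsets outermost, so all
            # copies move large contiguous blocks
            cols = np.empty((3, 3, 3, C, B, D, H, W), dtype=x.dtype)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        cols[i, j, k] = np.moveaxis(
                            xp[:, :, i:i + D, j:j + H, k:k + W], 0, 1)
            colsf = cols.reshape(27 * C, B * D * H * W)
            wmat = np.ascontiguousarray(
                self.w.data.transpose(0, 2, 3, 4, 1)
            ).reshape(self.cout, 27 * C).astype(x.dtype)
            y = (wmat @ colsf).reshape(self.cout, B, D, H, W)
            y += self.b.data.astype(x.dtype)[:, None, None, None, None]
            self._cache = (xp, colsf, x.dtype)
            return np.ascontiguousarray(np.moveaxis(y, 0, 1))
        w = self.w.data.astype(x.dtype, copy=False)
        y = np.zeros((self.cout, B, D, H, W), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                slab = xp[:, :, i:i + D, j:j + H, :]
                for k in range(3):
                    y += np.tensordot(w[:, :, i, j, k],
                                      slab[..., k:k + W], axes=([1], [1]))
        y += self.b.data.astype(x.dtype)[:, None, None, None, None]
        self._cache = (xp, None, x.dtype)
        return np.moveaxis(y, 0, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, cols, xdtype = self._cache
        self._cache = None
        B = dy.shape[0]
        D, H, W = dy.shape[2:]
        C = self.cin
        if cols is not None:
            colsf = cols
            dyf = np.ascontiguousarray(np.moveaxis(dy, 0, 1)
                                       ).reshape(self.cout, -1)
            dw = (dyf @ colsf.T).reshape(self.cout, 3, 3, 3, C)
            self.w.grad += dw.transpose(0, 4, 1, 2, 3)
            self.b.grad += dyf.sum(axis=1)
            wmat = np.ascontiguousarray(
                self.w.data.transpose(0, 2, 3, 4, 1)
            ).reshape(self.cout, 27 * C).astype(dy.dtype)
            dcols = (wmat.T @ dyf).reshape(3, 3, 3, C, B, D, H, W)
            dxp = np.zeros_like(xp)
            for i in range(3):
                for j in range(3):
                    for k in range(3):
                        dxp[:, :, i:i + D, j:j + H, k:k + W] += \
                            np.moveaxis(dcols[i, j, k], 0, 1)
            return dxp[:, :, 1:-1, 1:-1, 1:-1].astype(xdtype, copy=False)
        w = self.w.data.astype(dy.dtype, copy=False)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                slab = xp[:, :, i:i + D, j:j + H, :]
                dslab = dxp[:, :, i:i + D, j:j + H, :]
                for k in range(3):
                    # (Cout, Cin) gradient: contract dy with the shifted input
                    self.w.grad[:, :, i, j, k] += np.tensordot(
                        dy, slab[..., k:k + W], axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                    # input gradient: scatter-add W^T dy into the shifted slab
                    dslab[..., k:k + W] += np.tensordot(
                        w[:, :, i, j, k], dy, axes=([0], [1])).transpose(1, 0, 2, 3, 4)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        return dxp[:, :, 1:-1, 1:-1, 1:-1].astype(xdtype, copy=False)


class InstanceNorm3d(Module):
    """Per-sample per-channel normalization over the (F, H, W) extent."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, x.shape)
        return xhat

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, shape = self._cache
        self._cache = None
        m = dy.mean(axis=(2, 3, 4), keepdims=True)
        mx = (dy * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return inv * (dy - m - xhat * mx)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dy, self.slope * dy)


class MaxPool1x2x2(Module):
    """Anisotropic 1x2x2 max pooling: halves H and W, preserves the F axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("H and W must be even for 1x2x2 pooling")
        v = x.reshape(B, C, D, H // 2, 2, W // 2, 2)
        v = v.transpose(0, 1, 2, 3, 5, 4, 6).reshape(B, C, D, H // 2, W // 2, 4)
        idx = v.argmax(axis=-1)
        y = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        self._cache = None
        B, C, D, H, W = shape
        dv = np.zeros((B, C, D, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dv, idx[..., None], dy[..., None], axis=-1)
        dv = dv.reshape(B, C, D, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6)
        return dv.reshape(B, C, D, H, W)


class ConvTranspose1x2x2(Module):
    """Transposed convolution, kernel (1,2,2), stride (1,2,2): doubles H, W."""

    def __init__(self, cin: int, cout: int, seed: int, name: str):
        rng = layer_rng(seed, name)
        std = np.sqrt(2.0 / cin)
        self.w = Param(f"{name}.w", rng.normal(0.0, std, size=(cin, cout, 2, 2)))
        self.b = Param(f"{name}.b", np.zeros(cout))
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, D, H, W = x.shape
        y = np.einsum("bcdhw,coij->bodhiwj", x, self.w.data.astype(x.dtype),
                      optimize=True)
        y = y.reshape(B, self.cout, D, 2 * H, 2 * W)
        y += self.b.data.astype(x.dtype)[None, :, None, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        B, C, D, H, W = x.shape
        dyb = dy.reshape(B, self.cout, D, H, 2, W, 2)
        self.w.grad += np.einsum("bcdhw,bodhiwj->coij", x, dyb, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        return np.einsum("bodhiwj,coij->bcdhw", dyb,
                         self.w.data.astype(dy.dtype), optimize=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SpectralSE(Module):
    """Spectral squeeze-and-excitation channel reweighting.

    Squeeze averages over the spatial extent only, keeping a per-energy
    (B, C, F) descriptor; the two-layer excitation bottleneck (reduction r,
    leaky ReLU, sigmoid) is shared across energy indices, yielding a gate
    in (0,1) per (channel, bin) that rescales the features.
    """

    def __init__(self, channels: int, seed: int, name: str,
                 reduction: int = 8, leaky_slope: float = 0.01):
        hidden = max(1, channels // reduction)
        rng = layer_rng(seed, name)
        self.w1 = Param(f"{name}.w1",
                        rng.normal(0, np.sqrt(2.0 / channels), (hidden, channels)))
        self.b1 = Param(f"{name}.b1", np.zeros(hidden))
        self.w2 = Param(f"{name}.w2",
                        rng.normal(0, np.sqrt(2.0 / hidden), (channels, hidden)))
        self.b2 = Param(f"{name}.b2", np.zeros(channels))
        self.slope = leaky_slope

    def forward(self, u: np.ndarray) -> np.ndarray:
        B, C, D, H, W = u.shape
        s = u.mean(axis=(3, 4))                       # (B, C, F)
        z1 = np.einsum("bcf,hc->bhf", s, self.w1.data.astype(u.dtype)) \
            + self.b1.data.astype(u.dtype)[None, :, None]
        a1 = np.where(z1 >= 0, z1, self.slope * z1)
        z2 = np.einsum("bhf,ch->bcf", a1, self.w2.data.astype(u.dtype)) \
            + self.b2.data.astype(u.dtype)[None, :, None]
        g = _sigmoid(z2)
        self._cache = (u, s, z1, a1, g)
        return u * g[:, :, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u, s, z1, a1, g = self._cache
        self._cache = None
        B, C, D, H, W = u.shape
        du_direct = dy * g[:, :, :, None, None]
        dg = (dy * u).sum(axis=(3, 4))               # (B, C, F)
        dz2 = dg * g * (1.0 - g)
        self.w2.grad += np.einsum("bcf,bhf->ch", dz2, a1, optimize=True)
        self.b2.grad += dz2.sum(axis=(0, 2))
        da1 = np.einsum("bcf,ch->bhf", dz2, self.w2.data.astype(dy.dtype))
        dz1 = np.where(z1 >= 0, da1, self.slope * da1)
        self.w1.grad += np.einsum("bhf,bcf->hc", dz1, s, optimize=True)
        self.b1.grad += dz1.sum(axis=(0, 2))
        ds = np.einsum("bhf,hc->bcf", dz1, self.w1.data.astype(dy.dtype))
        return du_direct + ds[:, :, :, None, None] / (H * W)

    def gate(self, u: np.ndarray) -> np.ndarray:
        """Gate values alone (for tests/inspection)."""
        y = self.forward(u)
        g = self._cache[4]
        self._cache = None
        return g


def sinusoidal_encoding(F: int, dim: int) -> np.ndarray:
    """(F, dim) positional encoding of the energy-bin index."""
    pos = np.arange(F)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :]
    freq = 1.0 / (10000.0 ** (2 * i / dim))
    enc = np.zeros((F, dim))
    enc[:, 0::2] = np.sin(pos * freq)
    enc[:, 1::2] = np.cos(pos * freq)
    return enc


class EnergyFiLM(Module):
    """Per-energy-bin affine feature modulation (FiLM).

    A two-layer perceptron maps a sinusoidal encoding of the bin index to
    (dgamma_f, beta_f) in R^{2C}; the output is (1 + dgamma) * u + beta,
    broadcast over (H, W).  The final layer is zero-initialized, so the
    module is exactly the identity at initialization.
    """

    def __init__(self, channels: int, F: int, seed: int, name: str,
                 enc_dim: int = 16, leaky_slope: float = 0.01):
        rng = layer_rng(seed, name)
        self.enc = sinusoidal_encoding(F, enc_dim).astype(np.float32)
        self.w1 = Param(f"{name}.w1",
                        rng.normal(0, np.sqrt(2.0 / enc_dim), (enc_dim, enc_dim)))
        self.b1 = Param(f"{name}.b1", np.zeros(enc_dim))
        self.w2 = Param(f"{name}.w2", np.zeros((2 * channels, enc_dim)))
        self.b2 = Param(f"{name}.b2", np.zeros(2 * channels))
        self.channels = channels
        self.slope = leaky_slope

    def _film_params(self, dtype) -> tuple:
        z1 = self.enc.astype(dtype) @ self.w1.data.T.astype(dtype) \
            + self.b1.data.astype(dtype)          # (F, enc_dim)
        a1 = np.where(z1 >= 0, z1, self.slope * z1)
        z2 = a1 @ self.w2.data.T.astype(dtype) + self.b2.data.astype(dtype)
        dgamma = z2[:, : self.channels]           # (F, C)
        beta = z2[:, self.channels:]
        return z1, a1, dgamma, beta

    def forward(self, u: np.ndarray) -> np.ndarray:
        z1, a1, dgamma, beta = self._film_params(u.dtype)
        gamma = 1.0 + dgamma.T                    # (C, F)
        self._cache = (u, z1, a1, gamma)
        return gamma[None, :, :, None, None] * u \
            + beta.T[None, :, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u, z1, a1, gamma = self._cache
        self._cache = None
        du = dy * gamma[None, :, :, None, None]
        dgamma = (dy * u).sum(axis=(0, 3, 4)).T   # (F, C)
        dbeta = dy.sum(axis=(0, 3, 4)).T          # (F, C)
        dz2 = np.concatenate([dgamma, dbeta], axis=1)  # (F, 2C)
        self.w2.grad += dz2.T @ a1
        self.b2.grad += dz2.sum(axis=0)
        da1 = dz2 @ self.w2.data.astype(dy.dtype)
        dz1 = np.where(z1 >= 0, da1, self.slope * da1)
        self.w1.grad += dz1.T @ self.enc.astype(dy.dtype)
        self.b1.grad += dz1.sum(axis=0)
        return du


def _rfft_matrices(F: int) -> tuple:
    """Real/imag analysis (K, F) and synthesis (K, F) matrices of the rFFT."""
    K = F // 2 + 1
    k = np.arange(K)[:, None]
    f = np.arange(F)[None, :]
    ang = 2.0 * np.pi * k * f / F
    a_re = np.cos(ang)
    a_im = -np.sin(ang)
    # synthesis rows: irfft of the unit real / unit imaginary coefficient
    s_re = np.zeros((K, F))
    s_im = np.zeros((K, F))
    for kk in range(K):
        c = np.zeros(K, dtype=complex)
        c[kk] = 1.0
        s_re[kk] = np.fft.irfft(c, n=F)
        c[kk] = 1.0j
        s_im[kk] = np.fft.irfft(c, n=F)
    return a_re, a_im, s_re, s_im


class FourierGate(Module):
    """Frequency-domain gating of the global spectral profile.

    The per-sample profile s in R^F (mean of u over channels and space) is
    transformed with a real FFT along the energy axis, each of the
    floor(F/2)+1 coefficients is scaled by a learnable nonnegative mask
    (initialized to ones, clipped at zero when applied), and the inverse
    transform gives a gate w in R^{B x F} that multiplicatively rescales u.
    With the mask at its initialization the gate equals s itself.
    """

    def __init__(self, F: int, seed: int, name: str):
        K = F // 2 + 1
        self.mask = Param(f"{name}.mask", np.ones(K))
        a_re, a_im, s_re, s_im = _rfft_matrices(F)
        self.a_re = a_re.astype(np.float32)
        self.a_im = a_im.astype(np.float32)
        self.s_re = s_re.astype(np.float32)
        self.s_im = s_im.astype(np.float32)
        self.F = F

    def forward(self, u: np.ndarray) -> np.ndarray:
        B, C, D, H, W = u.shape
        s = u.mean(axis=(1, 3, 4))                      # (B, F)
        dt = u.dtype
        S_re = s @ self.a_re.T.astype(dt)               # (B, K)
        S_im = s @ self.a_im.T.astype(dt)
        m = np.maximum(self.mask.data, 0.0).astype(dt)
        w = (S_re * m) @ self.s_re.astype(dt) + (S_im * m) @ self.s_im.astype(dt)
        self._cache = (u, s, S_re, S_im, w)
        return u * w[:, None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u, s, S_re, S_im, w = self._cache
        self._cache = None
        B, C, D, H, W = u.shape
        dt = dy.dtype
        du_direct = dy * w[:, None, :, None, None]
        dw = (dy * u).sum(axis=(1, 3, 4))               # (B, F)
        dMre = dw @ self.s_re.T.astype(dt)              # (B, K)
        dMim = dw @ self.s_im.T.astype(dt)
        active = (self.mask.data > 0).astype(dt)        # subgradient of clip
        self.mask.grad += ((dMre * S_re + dMim * S_im).sum(axis=0) * active)
        m = np.maximum(self.mask.data, 0.0).astype(dt)
        ds = (dMre * m) @ self.a_re.astype(dt) + (dMim * m) @ self.a_im.astype(dt)
        return du_direct + ds[:, None, :, None, None] / (C * H * W)

    def gate(self, u: np.ndarray) -> np.ndarray:
        y = self.forward(u)
        w = self._cache[4]
        self._cache = None
        return w


class SpectralFusionHead(Module):
    """Fuse the preserved energy axis into class logits.

    A single convolution with kernel extent (F, 1, 1) and no padding along
    the energy axis maps (B, C_feat, F, H, W) to (B, n_classes, H, W): a
    per-voxel linear read-out of the full spectral feature stack.
    """

    def __init__(self, cin: int, n_classes: int, F: int, seed: int, name: str):
        rng = layer_rng(seed, name)
        std = np.sqrt(2.0 / (cin * F))
        self.w = Param(f"{name}.w", rng.normal(0, std, (n_classes, cin, F)))
        self.b = Param(f"{name}.b", np.zeros(n_classes))
        self.F = F

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.F:
            raise ValueError(f"energy extent {x.shape[2]} != expected {self.F}")
        y = np.einsum("bcfhw,ocf->bohw", x, self.w.data.astype(x.dtype),
                      optimize=True)
        y += self.b.data.astype(x.dtype)[None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.w.grad += np.einsum("bohw,bcfhw->ocf", dy, x, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("bohw,ocf->bcfhw", dy, self.w.data.astype(dy.dtype),
                         optimize=True)
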