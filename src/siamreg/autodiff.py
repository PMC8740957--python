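"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations a 3-D fully
convolutional registration network needs: elementwise arithmetic,
reductions, same-padded 3-D convolution (im2col + GEMM), 2x2x2 max-pooling,
nearest-neighbour up-sampling, channel concatenation, spatial zero-padding,
separable Gaussian smoothing, finite-difference stencils and a trilinear
grid sampler differentiable with respect to the sampling displacements.

Tensors wrap ``ndarray`` data and build a DAG as expressions are composed;
``Tensor.backward()`` runs the reverse sweep.  Feature grids are laid out
channel-first, ``(C, D, H, W)``.  Gradients are only propagated into nodes
whose ``requires_grad`` flag is set (directly or through a parent), so leaf
image data never pays for a gradient pass.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "Tensor",
    "as_tensor",
    "relu",
    "leaky_relu",
    "tsum",
    "tmean",
    "tsqrt",
    "conv3d",
    "maxpool3d",
    "upsample_nearest3d",
    "pad_spatial",
    "concat_channels",
    "gaussian_smooth3d",
    "forward_diff",
    "second_diff",
    "grid_sample",
    "trilinear_sample",
]

_FLOATS = (np.float32, np.float64)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.type not in _FLOATS:
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper for op results ------------------------------
    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- properties -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def backward(self):
        """Run the reverse sweep from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free the tape as we go; parents keep their grads
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        return Tensor._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / reductions
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x._accum(g * mask)

    return Tensor._node(out_data, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    """LeakyReLU; the negative slope keeps units trainable (a plain ReLU
    net this small can die wholesale under aggressive optimizer steps)."""
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x._accum(g * np.where(mask, 1.0, slope))

    return Tensor._node(out_data, (x,), backward)


def tsum(x: Tensor, axis=None) -> Tensor:
    out_data = x.data.sum(axis=axis)

    def backward(g):
        if axis is None:
            x._accum(np.broadcast_to(g, x.data.shape))
        else:
            x._accum(np.broadcast_to(np.expand_dims(g, axis), x.data.shape))

    return Tensor._node(out_data, (x,), backward)


def tmean(x: Tensor) -> Tensor:
    return tsum(x) / float(x.data.size)


def tsqrt(x: Tensor, eps: float = 1e-20) -> Tensor:
    """Square root with a guarded derivative at zero (subgradient 0 is not
    needed here; the guard keeps constant displacement fields finite)."""
    out_data = np.sqrt(x.data)

    def backward(g):
        x._accum(g * 0.5 / np.maximum(out_data, eps))

    return Tensor._node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution and friends (channel-first (C, D, H, W) grids)
# ---------------------------------------------------------------------------


_COLS_ARENA: dict[str, np.ndarray | None] = {"buf": None}


def _arena_matrix(rows: int, cols: int, dtype) -> np.ndarray:
    """A reusable scratch matrix for im2col.  Convolutions execute strictly
    sequentially and the unfolded matrix is consumed before the next one is
    built, so a single grow-only buffer avoids repeated large allocations."""
    need = rows * cols * np.dtype(dtype).itemsize
    buf = _COLS_ARENA["buf"]
    if buf is None or buf.nbytes < need:
        buf = np.empty(need, dtype=np.uint8)
        _COLS_ARENA["buf"] = buf
    return buf[:need].view(dtype).reshape(rows, cols)


def _im2col(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """Zero-pad ``x`` (C, D, H, W) for same-size output and unfold into a
    ``(C*kd*kh*kw, D*H*W)`` matrix (in the shared arena) whose row order
    matches a flattened (O, C, kd, kh, kw) weight tensor."""
    kd, kh, kw = kernel
    c, d, h, w = x.shape
    xp = np.pad(
        x, ((0, 0), (kd // 2, kd // 2), (kh // 2, kh // 2), (kw // 2, kw // 2))
    )
    cols = _arena_matrix(c * kd * kh * kw, d * h * w, x.dtype)
    r = 0
    for ci in range(c):
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    np.copyto(
                        cols[r].reshape(d, h, w), xp[ci, i : i + d, j : j + h, k : k + w]
                    )
                    r += 1
    return cols


def _conv3d_data(x: np.ndarray, w: np.ndarray):
    """Same-padded correlation of (C,D,H,W) with (O,C,kd,kh,kw).  Returns
    the output and the (arena-backed, transient) im2col matrix."""
    o = w.shape[0]
    kernel = w.shape[2:]
    cols = _im2col(x, kernel)
    out = w.reshape(o, -1) @ cols  # (O, N)
    d, h, ww = x.shape[1:]
    return out.reshape(o, d, h, ww), cols


def _fft_shape(spatial, kernel):
    from scipy.fft import next_fast_len

    return tuple(next_fast_len(d + k - 1) for d, k in zip(spatial, kernel))


def _conv3d_fft(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded correlation via FFT; used for large kernels where the
    im2col matrix would be enormous."""
    from scipy.fft import irfftn, rfftn

    spatial = x.shape[1:]
    kernel = w.shape[2:]
    s = _fft_shape(spatial, kernel)
    xf = rfftn(x, s=s, axes=(1, 2, 3))
    wf = rfftn(w[:, :, ::-1, ::-1, ::-1], s=s, axes=(2, 3, 4))
    yf = (wf * xf[None]).sum(axis=1)
    y = irfftn(yf, s=s, axes=(1, 2, 3))
    p = [k // 2 for k in kernel]
    out = y[
        :,
        p[0] : p[0] + spatial[0],
        p[1] : p[1] + spatial[1],
        p[2] : p[2] + spatial[2],
    ]
    return np.ascontiguousarray(out).astype(x.dtype, copy=False)


def _conv3d_fft_wgrad(x: np.ndarray, go: np.ndarray, kernel) -> np.ndarray:
    """Weight gradient of the FFT correlation: for every (out, in) channel
    pair, the cross-correlation of input and output-gradient restricted to
    kernel offsets.  The FFT length exceeds data + kernel support, so the
    circular wrap never aliases the offsets that are read."""
    from scipy.fft import irfftn, rfftn

    s = _fft_shape(x.shape[1:], kernel)
    xf = rfftn(x, s=s, axes=(1, 2, 3))
    gof = rfftn(go, s=s, axes=(1, 2, 3))
    cc = irfftn(xf[None] * np.conj(gof)[:, None], s=s, axes=(2, 3, 4))
    p = [k // 2 for k in kernel]
    idx = [np.arange(-pi, ki - pi) % si for pi, ki, si in zip(p, kernel, s)]
    return cc[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]].astype(
        x.dtype, copy=False
    )


_FFT_KERNEL_THRESHOLD = 28  # kernels with more taps than this go through FFT


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 3-D convolution (cross-correlation) with odd kernels.

    ``x``: (C, D, H, W); ``w``: (O, C, kd, kh, kw); ``b``: (O,) or None.
    Small kernels run as im2col + GEMM (the matrix is kept on the tape for
    the weight-gradient GEMM); large kernels run through FFT.
    """
    if x.ndim != 4 or w.ndim != 5 or x.shape[0] != w.shape[1]:
        raise ValueError(
            f"conv3d shape mismatch: input {x.shape}, weight {w.shape}"
        )
    kernel = w.shape[2:]
    if any(k % 2 == 0 for k in kernel):
        raise ValueError("conv3d requires odd kernel extents")
    use_fft = int(np.prod(kernel)) > _FFT_KERNEL_THRESHOLD
    if use_fft:
        out_data = _conv3d_fft(x.data, w.data)
    else:
        out_data, _ = _conv3d_data(x.data, w.data)
    if b is not None:
        out_data += b.data[:, None, None, None]
    parents = (x, w) if b is None else (x, w, b)
    spatial = x.shape[1:]
    o, c = w.shape[:2]
    k3 = int(np.prod(kernel))

    def backward(g):
        go = np.ascontiguousarray(g.reshape((o,) + spatial))
        if b is not None:
            b._accum(g.sum(axis=(1, 2, 3)))
        if use_fft:
            w._accum(_conv3d_fft_wgrad(x.data, go, kernel))
            if x.requires_grad:
                w_rot = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                )
                x._accum(_conv3d_fft(go, w_rot))
            return
        # one unfolding of the output gradient serves both gradients:
        #   dL/dw[o,c,t] = <cols_go[o, flip(t)], x_c>   (spatially flipped taps)
        #   dL/dx       = w_rot @ cols_go               (full correlation)
        cols_go = _im2col(go, kernel)
        gw = (cols_go @ x.data.reshape(c, -1).T).reshape((o,) + kernel + (c,))
        gw = gw[:, ::-1, ::-1, ::-1].transpose(0, 4, 1, 2, 3)
        w._accum(np.ascontiguousarray(gw))
        if x.requires_grad:
            w_rot = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            gx = (w_rot.reshape(c, -1) @ cols_go).reshape((c,) + spatial)
            x._accum(gx)

    return Tensor._node(out_data, parents, backward)


def maxpool3d(x: Tensor) -> Tensor:
    """2x2x2 max-pooling; every spatial extent must be even."""
    c, d, h, w = x.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"maxpool3d needs even extents, got {(d, h, w)}")
    win = (
        x.data.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, d // 2, h // 2, w // 2, 8)
    )
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = (
            gwin.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )
        x._accum(gx)

    return Tensor._node(out_data, (x,), backward)


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    c, d, h, w = x.shape
    out_data = (
        x.data.repeat(factor, axis=1).repeat(factor, axis=2).repeat(factor, axis=3)
    )

    def backward(g):
        gx = g.reshape(c, d, factor, h, factor, w, factor).sum(axis=(2, 4, 6))
        x._accum(gx)

    return Tensor._node(out_data, (x,), backward)


def pad_spatial(x: Tensor, pads) -> Tensor:
    """Zero-pad the three trailing spatial axes; ``pads`` is three
    (before, after) pairs."""
    (b0, a0), (b1, a1), (b2, a2) = pads
    if min(b0, a0, b1, a1, b2, a2) < 0:
        raise ValueError(f"negative pad amounts: {pads}")
    out_data = np.pad(x.data, ((0, 0), (b0, a0), (b1, a1), (b2, a2)))
    d, h, w = x.shape[1:]

    def backward(g):
        x._accum(g[:, b0 : b0 + d, b1 : b1 + h, b2 : b2 + w])

    return Tensor._node(out_data, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=0)
    sizes = [t.shape[0] for t in tensors]

    def backward(g):
        start = 0
        for t, n in zip(tensors, sizes):
            t._accum(g[start : start + n])
            start += n

    return Tensor._node(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# separable smoothing and finite differences
# ---------------------------------------------------------------------------


def gaussian_smooth3d(x: Tensor, taps: np.ndarray) -> Tensor:
    """Separable convolution with a symmetric 1-D kernel along the three
    trailing axes, zero boundary extension.  The kernel is constant (no
    gradient w.r.t. taps); symmetry makes the adjoint the same convolution.
    """
    taps = np.asarray(taps, dtype=x.dtype)
    axes = tuple(range(x.ndim - 3, x.ndim))

    def smooth(a):
        for ax in axes:
            a = convolve1d(a, taps, axis=ax, mode="constant", cval=0.0)
        return a

    out_data = smooth(x.data)

    def backward(g):
        x._accum(smooth(g))

    return Tensor._node(out_data, (x,), backward)


def forward_diff(x: Tensor, axis: int) -> Tensor:
    """Forward difference along ``axis`` with zero at the trailing edge
    (same output shape)."""
    d = np.zeros_like(x.data)
    src = [slice(None)] * x.ndim
    dst = [slice(None)] * x.ndim
    src[axis] = slice(1, None)
    dst[axis] = slice(None, -1)
    d[tuple(dst)] = x.data[tuple(src)] - x.data[tuple(dst)]

    def backward(g):
        gx = np.zeros_like(g)
        gx[tuple(src)] += g[tuple(dst)]
        gx[tuple(dst)] -= g[tuple(dst)]
        x._accum(gx)

    return Tensor._node(d, (x,), backward)


def second_diff(x: Tensor, axis: int) -> Tensor:
    """Second-order central difference along ``axis``; output loses the two
    boundary slices (valid region only, so affine fields map to exact zero)."""
    n = x.shape[axis]
    if n < 3:
        raise ValueError("second_diff needs extent >= 3")
    sl = lambda a, b: tuple(
        slice(a, b) if i == axis % x.ndim else slice(None) for i in range(x.ndim)
    )
    d = x.data[sl(2, None)] - 2 * x.data[sl(1, -1)] + x.data[sl(None, -2)]

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl(2, None)] += g
        gx[sl(1, -1)] -= 2 * g
        gx[sl(None, -2)] += g
        x._accum(gx)

    return Tensor._node(d, (x,), backward)


# ---------------------------------------------------------------------------
# trilinear sampling (the spatial transformer)
# ---------------------------------------------------------------------------


def _corner_values(vol: np.ndarray, x0, valid_needed: bool):
    """Gather the 8 corner values around integer base indices ``x0``
    (3, N).  Returns ``vals[dz][dy][dx]`` of shape (C, N) with out-of-range
    corners zeroed, plus the per-corner validity masks."""
    dims = vol.shape[1:]
    vals = {}
    for d0 in (0, 1):
        for d1 in (0, 1):
            for d2 in (0, 1):
                i = x0[0] + d0
                j = x0[1] + d1
                k = x0[2] + d2
                valid = (
                    (i >= 0)
                    & (i < dims[0])
                    & (j >= 0)
                    & (j < dims[1])
                    & (k >= 0)
                    & (k < dims[2])
                )
                ic = np.clip(i, 0, dims[0] - 1)
                jc = np.clip(j, 0, dims[1] - 1)
                kc = np.clip(k, 0, dims[2] - 1)
                v = vol[:, ic, jc, kc]
                if valid_needed:
                    v = v * valid
                vals[(d0, d1, d2)] = v
    return vals


def trilinear_sample(
    vol: np.ndarray, coords: np.ndarray, oob: str = "zero", want_grad: bool = False
):
    """Trilinearly sample ``vol`` (C, D, H, W) at voxel ``coords`` (3, N).

    ``oob='zero'`` treats the volume as zero outside its grid; ``'border'``
    clamps coordinates to the boundary.  When ``want_grad`` is true, also
    returns ``d out / d coords`` of shape (3, C, N) (zero wherever a
    clamped coordinate saturates).
    """
    if oob not in ("zero", "border"):
        raise ValueError(f"unknown oob policy {oob!r}")
    dims = np.array(vol.shape[1:])
    coords = np.asarray(coords, dtype=vol.dtype)
    if oob == "border":
        inside = [
            (coords[a] > 0) & (coords[a] < dims[a] - 1) for a in range(3)
        ]
        coords = np.minimum(
            np.maximum(coords, 0), (dims - 1)[:, None].astype(vol.dtype)
        )
    x0 = np.floor(coords).astype(np.int64)
    if oob == "border":
        # keep x0+1 in range so frac stays the exact interpolation weight
        x0 = np.minimum(x0, (dims - 2)[:, None])
        x0 = np.maximum(x0, 0)
    frac = coords - x0
    vals = _corner_values(vol, x0, valid_needed=(oob == "zero"))
    # weight along axis a for corner offset d: (1-frac[a]) if d == 0 else frac[a]
    wgt = (1.0 - frac, frac)
    out = np.zeros((vol.shape[0], coords.shape[1]), dtype=vol.dtype)
    for (d0, d1, d2), v in vals.items():
        out += v * (wgt[d0][0] * wgt[d1][1] * wgt[d2][2])
    if not want_grad:
        return out
    grad = np.zeros((3, vol.shape[0], coords.shape[1]), dtype=vol.dtype)
    for (d0, d1, d2), v in vals.items():
        s0 = 1.0 if d0 else -1.0
        s1 = 1.0 if d1 else -1.0
        s2 = 1.0 if d2 else -1.0
        grad[0] += v * (s0 * wgt[d1][1] * wgt[d2][2])
        grad[1] += v * (wgt[d0][0] * s1 * wgt[d2][2])
        grad[2] += v * (wgt[d0][0] * wgt[d1][1] * s2)
    if oob == "border":
        for a in range(3):
            grad[a] *= inside[a]
    return out, grad


def grid_sample(vol: np.ndarray, dvf: Tensor, oob: str = "zero") -> Tensor:
    """Warp ``vol`` (C, Dm, Hm, Wm) by the displacement field ``dvf``
    (3, D, H, W): output voxel x takes the value of ``vol`` at ``x + u(x)``
    in voxel coordinates.  Differentiable w.r.t. the displacement field only
    (the warped volume is input data, not a learnable quantity).
    """
    if dvf.shape[0] != 3 or dvf.ndim != 4:
        raise ValueError(f"displacement tensor must be (3, D, H, W), got {dvf.shape}")
    vol = np.asarray(vol)
    if vol.ndim == 3:
        vol = vol[None]
    vol = vol.astype(dvf.dtype, copy=False)
    spatial = dvf.shape[1:]
    base = np.stack(
        np.meshgrid(*[np.arange(s, dtype=dvf.dtype) for s in spatial], indexing="ij")
    ).reshape(3, -1)
    coords = base + dvf.data.reshape(3, -1)
    out, dcoords = trilinear_sample(vol, coords, oob=oob, want_grad=True)
    out_data = out.reshape((vol.shape[0],) + spatial)

    def backward(g):
        go = g.reshape(vol.shape[0], -1)
        gu = (dcoords * go[None]).sum(axis=1)  # (3, N)
        dvf._accum(gu.reshape(dvf.shape))

    return Tensor._node(out_data, (dvf,), backward)
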