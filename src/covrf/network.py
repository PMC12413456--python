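"""Scale-channel tracking network over event streams.

Architecture: four convolutional blocks.  Blocks 1-3 are replicated across
parallel temporal scale channels; each block is a spatial convolution
followed by a temporal activation whose time constant is the channel's
mu_k (leaky integrator + ReLU for the LI variant, leaky integrate-and-fire
for the LIF variant, or a stateless ReLU for the frame-based baselines).
Block 4 merges all channels with a 1x1 convolution and produces one
activation map per tracked shape; a differentiable coordinate head (soft
argmax) turns each map into (x, y) coordinates, and the head's temporal
smoothing uses leaky integrators in every variant.

Everything is implemented directly on NumPy arrays with hand-derived
reverse-mode gradients (exponential-Euler scans unrolled through time for
backpropagation through time; surrogate gradients for the spiking
Heaviside), so the models train on a plain CPU without a deep-learning
framework.  Tensors are time-major: event input is (B, T, 2, H, W).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .spatial import KernelBank
from .temporal import TemporalScaleBank, log_time_constants

__all__ = [
    "NetworkConfig",
    "ScaleChannelNet",
    "build_model",
    "initialize_rf",
    "initialize_uniform",
    "coordinate_transform",
]

VARIANTS = ("LI", "LIF", "ReLU-SF", "ReLU-MF")


@dataclass
class NetworkConfig:
    """Hyper-parameters of the scale-channel network."""

    n_scale_channels: int = 4
    kernels_per_block: int = 144
    kernel_size: int = 9
    kernel_size_late: int | None = None  # blocks 2-3; defaults to kernel_size
    n_output_shapes: int = 3
    variant: str = "LI"
    init: str = "rf"
    mf_frames: int = 8
    use_batchnorm: bool = False
    resolution: int = 300
    strides: tuple[int, int, int] = (2, 2, 2)
    input_gain: float = 1.0
    head_weighting: str = "linear"  # or "softmax"
    head_temperature: float = 1.0
    surrogate_slope: float = 10.0
    theta_thr: float = 1.0
    theta_reset: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.init not in ("rf", "uniform"):
            raise ValueError("init must be 'rf' or 'uniform'")
        if min(self.n_scale_channels, self.kernels_per_block,
               self.n_output_shapes, self.mf_frames) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def in_channels(self) -> int:
        return 2 * self.mf_frames if self.variant == "ReLU-MF" else 2

    @property
    def k_late(self) -> int:
        return self.kernel_size_late or self.kernel_size


# ---------------------------------------------------------------------------
# convolution primitives (batched over flattened time)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int):
    """(N, C, H, W) -> patches (N*Ho*Wo, C*k*k) with same-style padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, k, k)
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = x_shape
    p = k // 2
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, ho, wo, c, k, k)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + ho * stride:stride, dj:dj + wo * stride:stride] += (
                cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            )
    return xp[:, :, p:p + h, p:p + w]


class _Conv:
    """Strided 2-D convolution (correlation) applied to every frame."""

    def __init__(self, weight: np.ndarray, stride: int):
        self.weight = np.asarray(weight)  # (Cout, Cin, k, k)
        self.stride = stride
        self.grad = np.zeros_like(self.weight)

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, Cin, H, W) with N = B*T
        cout, cin, k, _ = self.weight.shape
        cols, ho, wo = _im2col(x, k, self.stride)
        self._cols = cols
        self._x_shape = x.shape
        y = cols @ self.weight.reshape(cout, -1).T
        return y.reshape(x.shape[0], ho, wo, cout).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray, need_input_grad: bool = True):
        cout, cin, k, _ = self.weight.shape
        g = np.ascontiguousarray(
            gy.transpose(0, 2, 3, 1).reshape(-1, cout)
        )
        self.grad += (g.T @ self._cols).reshape(self.weight.shape)
        gx = None
        if need_input_grad:
            gcols = g @ self.weight.reshape(cout, -1)
            gx = _col2im(gcols, self._x_shape, k, self.stride)
        self._cols = None
        return gx


# ---------------------------------------------------------------------------
# temporal activations (scans over the time axis)
# ---------------------------------------------------------------------------


def event_im2col(
    frames: np.ndarray, k: int, stride: int, hw: tuple[int, int] | None = None
):
    """Sparse im2col of a binary event movie for the first convolution.

    ``frames`` is one movie, (T, Cin, H, W) with few nonzero entries.
    Returns a CSR matrix of shape (T*Ho*Wo, Cin*k*k) such that
    ``cols @ W.reshape(Cout, -1).T`` equals the dense strided convolution
    (same-style zero padding) of every frame.  The matrix depends only on
    the data, so it can be cached across training epochs.
    """
    from scipy import sparse

    t_sz, cin, h, w = frames.shape
    p = k // 2
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    tt, cc, yy, xx = np.nonzero(frames)
    vals = frames[tt, cc, yy, xx].astype(np.float32)
    yy = yy + p
    xx = xx + p
    rows_all, cols_all, data_all = [], [], []
    for ky in range(k):
        oy, ry = np.divmod(yy - ky, stride)
        oky = (ry == 0) & (oy >= 0) & (oy < ho)
        if not oky.any():
            continue
        for kx in range(k):
            ox, rx = np.divmod(xx - kx, stride)
            ok = oky & (rx == 0) & (ox >= 0) & (ox < wo)
            if not ok.any():
                continue
            rows_all.append(tt[ok] * (ho * wo) + oy[ok] * wo + ox[ok])
            cols_all.append(cc[ok] * k * k + ky * k + kx)
            data_all.append(vals[ok])
    if rows_all:
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        data = np.concatenate(data_all)
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        data = np.zeros(0, dtype=np.float32)
    mat = sparse.coo_matrix(
        (data, (rows, cols)), shape=(t_sz * ho * wo, cin * k * k)
    ).tocsr()
    mat.ho, mat.wo = ho, wo  # type: ignore[attr-defined]
    return mat


class _SparseConv:
    """First-layer convolution driven by a cached sparse im2col matrix."""

    def __init__(self, weight: np.ndarray, cols, gain: float = 1.0):
        self.weight = np.asarray(weight)
        self.cols = cols
        self.gain = gain
        self.grad = np.zeros_like(self.weight)

    def forward(self, ho: int, wo: int) -> np.ndarray:
        cout = self.weight.shape[0]
        y = self.cols @ self.weight.reshape(cout, -1).T
        if self.gain != 1.0:
            y = y * self.gain
        n = y.shape[0] // (ho * wo)
        return np.ascontiguousarray(
            y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
        )

    def backward(self, gy: np.ndarray, need_input_grad: bool = False):
        cout = self.weight.shape[0]
        g = np.ascontiguousarray(gy.transpose(0, 2, 3, 1).reshape(-1, cout))
        gw = (self.cols.T @ g).T.reshape(self.weight.shape)
        self.grad += self.gain * gw
        return None


class _LIScan:
    """Exponential-Euler leaky-integrator scan with a trainable scalar mu."""

    def __init__(self, mu: float, dt: float = 1.0):
        self.mu = float(mu)
        self.dt = dt
        self.grad_mu = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, ...)
        a = np.exp(-self.dt / self.mu)
        u = np.zeros_like(x)
        acc = np.zeros_like(x[:, 0])
        for t in range(x.shape[1]):
            acc = a * acc + (1.0 - a) * x[:, t]
            u[:, t] = acc
        self._x = x
        self._u = u
        return u

    def backward(self, gu: np.ndarray) -> np.ndarray:
        a = np.exp(-self.dt / self.mu)
        x, u = self._x, self._u
        tmax = x.shape[1]
        gx = np.empty_like(x)
        carry = np.zeros_like(x[:, 0])
        da = 0.0
        for t in range(tmax - 1, -1, -1):
            g = gu[:, t] + carry
            gx[:, t] = (1.0 - a) * g
            u_prev = u[:, t - 1] if t > 0 else np.zeros_like(u[:, 0])
            da += float(np.sum(g * (u_prev - x[:, t])))
            carry = a * g
        self.grad_mu += da * a * self.dt / self.mu**2
        self._x = self._u = None
        return gx


class _LIFScan:
    """Spiking scan: exponential-Euler membrane, Heaviside with fast-sigmoid
    surrogate gradient, reset-to-theta_reset (reset path detached)."""

    def __init__(self, mu: float, theta_thr: float, theta_reset: float,
                 slope: float, dt: float = 1.0):
        self.mu = float(mu)
        self.theta_thr = theta_thr
        self.theta_reset = theta_reset
        self.slope = slope
        self.dt = dt
        self.grad_mu = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.exp(-self.dt / self.mu)
        z = np.zeros_like(x)
        upre = np.zeros_like(x)
        acc = np.zeros_like(x[:, 0])
        for t in range(x.shape[1]):
            acc = a * acc + (1.0 - a) * x[:, t]
            upre[:, t] = acc
            sp = acc >= self.theta_thr
            z[:, t] = sp
            acc = np.where(sp, self.theta_reset, acc)
        self._x = x
        self._upre = upre
        self._z = z
        return z

    def backward(self, gz: np.ndarray) -> np.ndarray:
        a = np.exp(-self.dt / self.mu)
        x, upre, z = self._x, self._upre, self._z
        tmax = x.shape[1]
        gx = np.empty_like(x)
        carry = np.zeros_like(x[:, 0])  # dL/du_post at t
        da = 0.0
        for t in range(tmax - 1, -1, -1):
            surr = 1.0 / (1.0 + self.slope * np.abs(upre[:, t] - self.theta_thr)) ** 2
            g_upre = gz[:, t] * surr + carry * (1.0 - z[:, t])
            gx[:, t] = (1.0 - a) * g_upre
            if t > 0:
                u_prev = np.where(z[:, t - 1] > 0, self.theta_reset, upre[:, t - 1])
            else:
                u_prev = np.zeros_like(upre[:, 0])
            da += float(np.sum(g_upre * (u_prev - x[:, t])))
            carry = a * g_upre
        self.grad_mu += da * a * self.dt / self.mu**2
        self._x = self._upre = self._z = None
        return gx


class _BatchNorm:
    """Per-feature-channel standardization over batch, time and space.

    Stateless (statistics recomputed per forward pass, no affine
    parameters); used by the optional normalization study flag.
    """

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, C, H, W); normalize over all axes except C
        axes = (0, 1, 3, 4)
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._xhat = xhat
        self._inv = inv
        self._n = x.size // x.shape[2]
        return xhat

    def backward(self, gy: np.ndarray) -> np.ndarray:
        axes = (0, 1, 3, 4)
        xhat, inv, n = self._xhat, self._inv, self._n
        g_mean = gy.mean(axis=axes, keepdims=True)
        gx_hat_mean = (gy * xhat).mean(axis=axes, keepdims=True)
        gx = inv * (gy - g_mean - xhat * gx_hat_mean)
        self._xhat = self._inv = None
        return gx


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy * self._mask
        self._mask = None
        return g


# ---------------------------------------------------------------------------
# coordinate head
# ---------------------------------------------------------------------------


def coordinate_transform(
    maps: np.ndarray,
    weighting: str = "linear",
    temperature: float = 1.0,
    fallback: str = "center",
):
    """Differentiable spatial average of activation maps.

    For each map (last two axes, H x W) the output is sum_p w(p) * pos(p)
    with ``w`` a normalized non-negative weighting: ``linear`` divides the
    (non-negative) map by its mass, ``softmax`` applies a spatial softmax at
    the given temperature.  Positions are 0-based pixel centers, returned as
    (x, y).  An all-zero map under linear weighting falls back to the map
    center and sets the returned flag.

    Returns ``(coords, flags)`` with coords shaped like ``maps`` minus the
    two spatial axes plus a trailing 2.
    """
    maps = np.asarray(maps, dtype=float)
    h, w = maps.shape[-2:]
    lead = maps.shape[:-2]
    flat = maps.reshape(-1, h * w)
    xs = np.tile(np.arange(w, dtype=float), h)
    ys = np.repeat(np.arange(h, dtype=float), w)
    if weighting == "softmax":
        m = flat / temperature
        m = m - m.max(axis=1, keepdims=True)
        e = np.exp(m)
        wgt = e / e.sum(axis=1, keepdims=True)
        flags = np.zeros(flat.shape[0], dtype=bool)
    elif weighting == "linear":
        if (flat < -1e-9).any():
            raise ValueError("linear weighting requires non-negative maps")
        mass = flat.sum(axis=1, keepdims=True)
        flags = mass[:, 0] <= 0
        safe = np.where(mass > 0, mass, 1.0)
        wgt = flat / safe
        if flags.any():
            if fallback != "center":
                raise ValueError("all-zero map with no fallback")
            wgt[flags] = 1.0 / (h * w)
    else:
        raise ValueError("weighting must be 'linear' or 'softmax'")
    coords = np.stack([wgt @ xs, wgt @ ys], axis=-1)
    return coords.reshape(*lead, 2), flags.reshape(lead)


class _CoordHead:
    """Differentiable coordinate head, in map-pixel units.

    ``softmax``: spatial softmax weighting at a temperature.  ``linear``:
    rectify the map, add a tiny uniform mass epsilon (graceful fallback to
    the map center when the map is empty) and take the mass-normalized
    centroid; the centroid is invariant to the overall activation
    amplitude, which makes it robust for very sparse inputs.
    """

    def __init__(self, weighting: str = "linear", temperature: float = 1.0,
                 eps: float = 1e-6):
        self.weighting = weighting
        self.temperature = temperature
        self.eps = eps

    def forward(self, maps: np.ndarray) -> np.ndarray:
        h, w = maps.shape[-2:]
        lead = maps.shape[:-2]
        flat = maps.reshape(-1, h * w).astype(np.float64)
        if self.weighting == "softmax":
            m = flat / self.temperature
            m -= m.max(axis=1, keepdims=True)
            e = np.exp(m)
            wgt = e / e.sum(axis=1, keepdims=True)
            self._pos_mask = None
            self._mass = None
        else:
            pos = np.maximum(flat, 0.0) + self.eps
            mass = pos.sum(axis=1, keepdims=True)
            wgt = pos / mass
            self._pos_mask = flat > 0
            self._mass = mass
        xs = np.tile(np.arange(w, dtype=float), h)
        ys = np.repeat(np.arange(h, dtype=float), w)
        cx = wgt @ xs
        cy = wgt @ ys
        self._wgt, self._xs, self._ys = wgt, xs, ys
        self._cx, self._cy = cx, cy
        self._shape = maps.shape
        self._in_dtype = maps.dtype
        return np.stack([cx, cy], axis=-1).reshape(*lead, 2)

    def backward(self, gc: np.ndarray) -> np.ndarray:
        gc = gc.reshape(-1, 2)
        if self.weighting == "softmax":
            # d cx / d m_i = w_i (x_i - cx) / temperature
            gm = (
                gc[:, :1] * self._wgt * (self._xs[None, :] - self._cx[:, None])
                + gc[:, 1:] * self._wgt * (self._ys[None, :] - self._cy[:, None])
            ) / self.temperature
        else:
            # d cx / d m_i = (x_i - cx) / mass on the rectified support
            gm = (
                gc[:, :1] * (self._xs[None, :] - self._cx[:, None])
                + gc[:, 1:] * (self._ys[None, :] - self._cy[:, None])
            ) / self._mass
            gm *= self._pos_mask
        out = gm.reshape(self._shape).astype(self._in_dtype)
        self._wgt = self._pos_mask = None
        return out


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class ScaleChannelNet:
    """Four-block scale-channel coordinate-regression network.

    Parameters live in ``self.params`` (name -> array, plus scalar time
    constants in ``self.mus``); :meth:`forward` runs a whole movie batch and
    :meth:`backward` accumulates gradients for BPTT training.
    """

    #: compute dtype; float32 keeps training cheap, float64 available for
    #: numerical verification (gradient checking)
    dtype = np.float32

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.kernels_per_block
        s = config.n_scale_channels
        k = config.kernel_size
        cin = config.in_channels

        def he_uniform(shape):
            fan_in = int(np.prod(shape[1:]))
            lim = np.sqrt(3.0 / fan_in)
            return rng.uniform(-lim, lim, size=shape).astype(np.float32)

        kl = config.k_late
        self.params: dict[str, np.ndarray] = {}
        for ch in range(s):
            self.params[f"W1.{ch}"] = he_uniform((c, cin, k, k))
            self.params[f"W2.{ch}"] = he_uniform((c, c, kl, kl))
            self.params[f"W3.{ch}"] = he_uniform((c, c, kl, kl))
        self.params["W4"] = he_uniform((config.n_output_shapes, s * c, 1, 1))
        # time constants: 3 per scale channel + one for the head
        bank = log_time_constants(s) if s > 1 else log_time_constants(1)
        self.mus: dict[str, float] = {}
        for ch in range(s):
            for b in (1, 2):
                self.mus[f"mu{b}.{ch}"] = float(bank.mus[ch])
            self.mus[f"mu3.{ch}"] = float(bank.mus.min())
        self.mus["mu4"] = float(bank.mus.min())
        self.grads: dict[str, np.ndarray] = {}
        self.seed = seed

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: weights, time constants, config and seed in one .npz."""
        import json

        meta = json.dumps({"config": asdict(self.config), "seed": self.seed,
                           "mus": self.mus})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "ScaleChannelNet":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["strides"] = tuple(cfg_d["strides"])
            model = cls(NetworkConfig(**cfg_d), seed=meta["seed"])
            model.mus = {k: float(v) for k, v in meta["mus"].items()}
            for k in model.params:
                model.params[k] = data[k]
        return model

    def describe(self) -> str:
        """Human-readable architecture summary."""
        cfg = self.config
        lines = [
            f"ScaleChannelNet variant={cfg.variant} init={cfg.init}",
            f"  {cfg.n_scale_channels} temporal scale channels, "
            f"{cfg.kernels_per_block} kernels/block "
            f"({cfg.kernel_size}x{cfg.kernel_size} in block 1, "
            f"{cfg.k_late}x{cfg.k_late} in blocks 2-3), strides "
            f"{tuple(cfg.strides)}",
            f"  {cfg.n_output_shapes} output maps -> {cfg.head_weighting} "
            f"coordinate head at {cfg.resolution}x{cfg.resolution} px",
            "  time constants: "
            + ", ".join(f"{k}={v:.3g}" for k, v in sorted(self.mus.items())),
            f"  parameters: {sum(int(np.prod(v.shape)) for v in self.params.values())}",
        ]
        return "\n".join(lines)

    # -- parameter utilities ------------------------------------------------

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.mu_grads = {k: 0.0 for k in self.mus}

    def mu_values(self) -> dict[str, float]:
        return dict(self.mus)

    # -- forward / backward -------------------------------------------------

    def _stack_frames(self, frames: np.ndarray) -> np.ndarray:
        """For the multi-frame variant: concatenate the last mf frames."""
        mf = self.config.mf_frames
        b, t = frames.shape[:2]
        parts = []
        for d in range(mf):
            shifted = np.zeros_like(frames)
            if d == 0:
                shifted = frames
            else:
                shifted[:, d:] = frames[:, :-d]
            parts.append(shifted)
        return np.concatenate(parts, axis=2)

    def _make_activation(self, mu_key: str):
        cfg = self.config
        pre = [_BatchNorm()] if cfg.use_batchnorm else []
        if cfg.variant == "LI":
            return pre + [_LIScan(self.mus[mu_key], cfg.dt), _ReLU()]
        if cfg.variant == "LIF":
            return pre + [_LIFScan(self.mus[mu_key], cfg.theta_thr,
                                   cfg.theta_reset, cfg.surrogate_slope,
                                   cfg.dt)]
        return pre + [_ReLU()]

    def forward(
        self,
        frames: np.ndarray | None = None,
        train: bool = False,
        block1_cols=None,
        batch_shape: tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Movie batch (B, T, 2, H, W) -> coordinates (B, T, n_shapes, 2) px.

        Causal over time: the output at frame t depends only on frames <= t.
        Instead of a dense ``frames`` tensor, a cached sparse im2col matrix
        of the batch (see :func:`event_im2col`, movies stacked in batch
        order) can be passed via ``block1_cols`` together with
        ``batch_shape`` = (B, T); this skips the dense first convolution
        entirely (not available for the multi-frame variant).
        """
        cfg = self.config
        sparse_first = block1_cols is not None and cfg.variant != "ReLU-MF"
        if sparse_first:
            if batch_shape is None:
                raise ValueError("batch_shape required with block1_cols")
            b, t = batch_shape
            h = w = cfg.resolution
            x0 = None
        else:
            if frames is None:
                raise ValueError("frames required without block1_cols")
            if frames.ndim != 5 or frames.shape[2] != 2:
                raise ValueError("expected event input of shape (B, T, 2, H, W)")
            x0 = frames.astype(self.dtype)
            if cfg.input_gain != 1.0:
                x0 = x0 * self.dtype(cfg.input_gain)
            if cfg.variant == "ReLU-MF":
                x0 = self._stack_frames(x0)
            b, t = x0.shape[:2]
            h = w = x0.shape[-1]
        self._layers = []  # [(conv, [acts...]) per (channel, block)] + merge
        outs = []
        k1, s1 = cfg.kernel_size, cfg.strides[0]
        ho1 = (h + 2 * (k1 // 2) - k1) // s1 + 1
        for ch in range(cfg.n_scale_channels):
            x = x0
            for blk in (1, 2, 3):
                if blk == 1 and sparse_first:
                    conv = _SparseConv(
                        self.params["W1.%d" % ch], block1_cols,
                        gain=cfg.input_gain,
                    )
                    y = conv.forward(ho1, ho1)
                else:
                    conv = _Conv(
                        self.params[f"W{blk}.{ch}"], cfg.strides[blk - 1]
                    )
                    n = x.shape[0] * x.shape[1]
                    y = conv.forward(x.reshape(n, *x.shape[2:]))
                y = y.reshape(b, t, *y.shape[1:])
                acts = self._make_activation(f"mu{blk}.{ch}")
                for act in acts:
                    y = act.forward(y)
                self._layers.append((f"{blk}.{ch}", conv, acts))
                x = y
            outs.append(x)
        merged = np.concatenate(outs, axis=2)  # (B, T, S*C, h, w)
        self._split = [o.shape[2] for o in outs]
        conv4 = _Conv(self.params["W4"], 1)
        n = merged.shape[0] * merged.shape[1]
        y = conv4.forward(merged.reshape(n, *merged.shape[2:]))
        y = y.reshape(b, t, *y.shape[1:])
        head_li = _LIScan(self.mus["mu4"], cfg.dt)
        y = head_li.forward(y)
        self._conv4, self._head_li = conv4, head_li
        self._head = _CoordHead(cfg.head_weighting, cfg.head_temperature)
        coords_map = self._head.forward(y)  # map-pixel units
        self._map_hw = y.shape[-2:]
        # with same-style padding, map cell i is centered on input pixel
        # i * (product of strides)
        self._scale = float(np.prod(cfg.strides))
        coords = coords_map * self._scale
        if not train:
            self._layers = None
            self._conv4 = self._head_li = self._head = None
        return coords

    def backward(self, gcoords: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/dcoords (input px units)."""
        cfg = self.config
        g = (gcoords * self._scale).astype(np.float64)
        gmap = self._head.backward(g)
        gmap = self._head_li.backward(gmap)
        self.mu_grads["mu4"] += self._head_li.grad_mu
        b, t = gmap.shape[:2]
        n = b * t
        gmerged = self._conv4.backward(gmap.reshape(n, *gmap.shape[2:]))
        self.grads["W4"] += self._conv4.grad
        gmerged = gmerged.reshape(b, t, *gmerged.shape[1:])
        splits = np.cumsum(self._split)[:-1]
        gouts = np.split(gmerged, splits, axis=2)
        layer_map = {name: (conv, acts) for name, conv, acts in self._layers}
        for ch in range(cfg.n_scale_channels):
            gx = gouts[ch]
            for blk in (3, 2, 1):
                conv, acts = layer_map[f"{blk}.{ch}"]
                for act in reversed(acts):
                    gx = act.backward(gx)
                    if isinstance(act, (_LIScan, _LIFScan)):
                        self.mu_grads[f"mu{blk}.{ch}"] += act.grad_mu
                        act.grad_mu = 0.0
                nb, tb = gx.shape[:2]
                gx = conv.backward(
                    gx.reshape(nb * tb, *gx.shape[2:]),
                    need_input_grad=(blk > 1),
                )
                self.grads[f"W{blk}.{ch}"] += conv.grad
                if gx is not None:
                    gx = gx.reshape(nb, tb, *gx.shape[1:])
        self._layers = None
        self._conv4 = self._head_li = self._head = None


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_rf(
    model: ScaleChannelNet,
    bank: KernelBank,
    mus: TemporalScaleBank,
    bank2: KernelBank | None = None,
) -> ScaleChannelNet:
    """Set blocks 1-2 from the receptive-field bank; time constants from mus.

    Block-1 weights equal the bank kernels exactly (tiled over the input
    polarities); block-2 weights tile the bank kernels over the fan-in,
    scaled by 1/fan_in to preserve activation magnitude (``bank2``, if
    given, supplies block-2 kernels at a different mask size).  Blocks 3-4
    stay uniform random.  Channel k uses time constant mu_k; the block-3
    and head time constants are fixed to the fastest (smallest) mu.
    """
    cfg = model.config
    c = cfg.kernels_per_block
    if len(bank) != c:
        raise ValueError(
            f"bank size {len(bank)} does not match kernels_per_block {c}"
        )
    if mus.K < cfg.n_scale_channels:
        raise ValueError("need at least one time constant per scale channel")
    b2 = bank2 if bank2 is not None else bank
    if b2.size != cfg.k_late or len(b2) != c:
        raise ValueError(
            "block-2 bank must match kernels_per_block and the late kernel size"
        )
    kern = bank.kernels.astype(np.float32)
    kern2 = b2.kernels.astype(np.float32)
    for ch in range(cfg.n_scale_channels):
        w1 = np.repeat(kern[:, None, :, :], cfg.in_channels, axis=1)
        model.params[f"W1.{ch}"] = w1.copy()
        w2 = np.repeat(kern2[:, None, :, :], c, axis=1) / float(c)
        model.params[f"W2.{ch}"] = w2.astype(np.float32)
        mu_ch = float(mus.mus[ch])
        model.mus[f"mu1.{ch}"] = mu_ch
        model.mus[f"mu2.{ch}"] = mu_ch
        model.mus[f"mu3.{ch}"] = float(mus.mus.min())
    model.mus["mu4"] = float(mus.mus.min())
    return model


def initialize_uniform(
    model: ScaleChannelNet,
    bank: KernelBank,
    mus: TemporalScaleBank,
    seed: int = 0,
    bank2: KernelBank | None = None,
) -> ScaleChannelNet:
    """Uniform white-noise control in the same parameter domain as RF init.

    Spatial weights of blocks 1-2 are drawn uniformly between the min and
    max weight value the RF initialization would place in that layer; the
    time constants are drawn uniformly from [min mu, max mu].
    """
    cfg = model.config
    rng = np.random.default_rng(seed)
    kern = bank.kernels
    lo1, hi1 = float(kern.min()), float(kern.max())
    if bank2 is not None:
        lo2 = float(bank2.kernels.min()) / cfg.kernels_per_block
        hi2 = float(bank2.kernels.max()) / cfg.kernels_per_block
    else:
        lo2, hi2 = lo1 / cfg.kernels_per_block, hi1 / cfg.kernels_per_block
    for ch in range(cfg.n_scale_channels):
        model.params[f"W1.{ch}"] = rng.uniform(
            lo1, hi1, size=model.params[f"W1.{ch}"].shape
        ).astype(np.float32)
        model.params[f"W2.{ch}"] = rng.uniform(
            lo2, hi2, size=model.params[f"W2.{ch}"].shape
        ).astype(np.float32)
        for b in (1, 2, 3):
            model.mus[f"mu{b}.{ch}"] = float(
                rng.uniform(mus.mus.min(), mus.mus.max())
            )
    model.mus["mu4"] = float(rng.uniform(mus.mus.min(), mus.mus.max()))
    return model


def build_model(
    config: NetworkConfig,
    bank: KernelBank | None = None,
    mus: TemporalScaleBank | None = None,
    seed: int = 0,
    bank2: KernelBank | None = None,
) -> ScaleChannelNet:
    """Construct and initialize a scale-channel network.

    ``init='rf'`` requires a kernel bank matching ``kernels_per_block``;
    ``init='uniform'`` draws weights uniformly in the same per-layer domain.
    Deterministic per seed.
    """
    model = ScaleChannelNet(config, seed=seed)
    if mus is None:
        mus = log_time_constants(max(config.n_scale_channels, 1))
    if config.init == "rf":
        if bank is None:
            raise ValueError("rf initialization requires a kernel bank")
        initialize_rf(model, bank, mus, bank2=bank2)
    else:
        if bank is not None:
            initialize_uniform(model, bank, mus, seed=seed, bank2=bank2)
        # without a bank the He-uniform constructor weights stand
    return model
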