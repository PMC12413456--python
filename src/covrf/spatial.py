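"""Affine Gaussian derivative receptive fields over the image plane.

This module constructs scale-normalized affine Gaussian directional-derivative
kernels

    T_{phi^m1 perp-phi^m2, norm}(x; Sigma) =
        sigma_par^m1 * sigma_perp^m2 * d_phi^m1 d_perpphi^m2 g(x; s * Sigma),

where ``g`` is a two-dimensional Gaussian with positive-definite covariance
``Sigma`` whose eigendirections are the kernel orientation ``phi`` and its
orthogonal complement, and the directional derivatives are taken along those
eigendirections.  Scale normalization (gamma = 1) multiplies an m-th order
derivative by sigma^m so that response magnitudes are comparable across
scales.

Kernels are sampled on a supersampled grid and area-downsampled to a compact
(default 9x9) convolution mask; derivatives are realized by applying 3-point
central-difference masks to the sampled Gaussian.  ``build_bank`` assembles
the default bank of 144 kernels (4 orientations x 4 scales x 3 skews x 3
derivative configurations) used to initialize the tracking network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpatialKernelSpec",
    "KernelBank",
    "DEFAULT_DERIVATIVE_SET",
    "covariance_from_spec",
    "transform_covariance",
    "sample_kernel",
    "sample_kernel_highres",
    "build_bank",
]

#: Derivative configurations (m1, m2) relative to the kernel orientation:
#: first order along phi, first order along perp-phi, and the mixed second
#: order.  Together with 4 orientations, 4 scales and 3 skews this yields the
#: default 144-kernel bank.
DEFAULT_DERIVATIVE_SET: tuple[tuple[int, int], ...] = ((1, 0), (0, 1), (1, 1))


@dataclass(frozen=True)
class SpatialKernelSpec:
    """Parameters of one affine Gaussian derivative kernel.

    Attributes
    ----------
    orientation:
        Kernel orientation phi in radians; the first eigendirection of the
        covariance matrix.
    sigma_parallel, sigma_perp:
        Spatial scale parameters (px) along phi and perp-phi; the covariance
        eigenvalues are their squares.  Convention: sigma_parallel >=
        sigma_perp > 0.
    order_parallel, order_perp:
        Orders of spatial differentiation m1 (along phi) and m2 (along
        perp-phi); m1 + m2 <= 2.
    scale:
        Dimensionless multiplier s on the covariance matrix.
    gamma:
        Scale-normalization power; fixed to 1 in this model.
    """

    orientation: float
    sigma_parallel: float
    sigma_perp: float
    order_parallel: int = 0
    order_perp: int = 0
    scale: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma_parallel > 0 and self.sigma_perp > 0):
            raise ValueError("sigma_parallel and sigma_perp must be positive")
        if self.sigma_perp > self.sigma_parallel:
            raise ValueError(
                "eigenvalue ordering convention requires "
                "sigma_parallel >= sigma_perp"
            )
        if self.order_parallel < 0 or self.order_perp < 0:
            raise ValueError("derivative orders must be non-negative")
        if self.order_parallel + self.order_perp > 2:
            raise ValueError("derivative orders above 2 are unsupported")
        if self.scale <= 0:
            raise ValueError("scale multiplier must be positive")

    @property
    def order(self) -> int:
        return self.order_parallel + self.order_perp


def covariance_from_spec(spec: SpatialKernelSpec) -> np.ndarray:
    """Covariance matrix R(phi) diag(sigma_par^2, sigma_perp^2) R(phi)^T.

    The eigendirections of the returned 2x2 symmetric positive-definite
    matrix are phi and perp-phi.  The ``scale`` multiplier s is *not*
    applied here; it multiplies the covariance at sampling time.
    """
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    rot = np.array([[c, -s], [s, c]])
    lam = np.diag([spec.sigma_parallel**2, spec.sigma_perp**2])
    sigma = rot @ lam @ rot.T
    return 0.5 * (sigma + sigma.T)


def transform_covariance(sigma: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Transport a covariance matrix under an affine map: A Sigma A^T."""
    sigma = np.asarray(sigma, dtype=float)
    a = np.asarray(a, dtype=float)
    if sigma.shape != (2, 2) or a.shape != (2, 2):
        raise ValueError("expected 2x2 matrices")
    if abs(np.linalg.det(a)) < 1e-12:
        raise ValueError("affine matrix must be invertible")
    out = a @ sigma @ a.T
    return 0.5 * (out + out.T)


def _gaussian_grid(spec: SpatialKernelSpec, n: int, h: float) -> np.ndarray:
    """Sample g(x; s*Sigma) on an n x n centered grid with spacing h px."""
    sigma = spec.scale * covariance_from_spec(spec)
    inv = np.linalg.inv(sigma)
    coords = (np.arange(n) - (n - 1) / 2.0) * h
    x1 = coords[np.newaxis, :]  # x rightward along columns
    x2 = coords[:, np.newaxis]  # y downward along rows
    quad = inv[0, 0] * x1**2 + 2.0 * inv[0, 1] * x1 * x2 + inv[1, 1] * x2**2
    norm = 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(sigma)))
    return norm * np.exp(-0.5 * quad)


def _central_diff(grid: np.ndarray, axis: int, h: float) -> np.ndarray:
    """3-point central difference with zero padding outside the grid."""
    out = np.zeros_like(grid)
    fwd = np.roll(grid, -1, axis=axis)
    bwd = np.roll(grid, 1, axis=axis)
    # zero the wrapped-around boundary samples
    idx_first = [slice(None)] * grid.ndim
    idx_last = [slice(None)] * grid.ndim
    idx_first[axis] = 0
    idx_last[axis] = -1
    fwd[tuple(idx_last)] = 0.0
    bwd[tuple(idx_first)] = 0.0
    out = (fwd - bwd) / (2.0 * h)
    return out


def _directional_derivative(
    grid: np.ndarray, phi: float, h: float, perpendicular: bool = False
) -> np.ndarray:
    """d_phi = cos(phi) d_x1 + sin(phi) d_x2 (or the perp direction)."""
    dx1 = _central_diff(grid, axis=1, h=h)
    dx2 = _central_diff(grid, axis=0, h=h)
    if perpendicular:
        return -np.sin(phi) * dx1 + np.cos(phi) * dx2
    return np.cos(phi) * dx1 + np.sin(phi) * dx2


def sample_kernel_highres(
    spec: SpatialKernelSpec, n: int, h: float
) -> np.ndarray:
    """Scale-normalized derivative kernel sampled at resolution n, spacing h.

    Returns values of the continuous kernel times the cell area h^2, so that
    the grid sum approximates the kernel integral.  No downsampling and no
    discrete renormalization is applied; use this for numerical experiments
    where the kernel support must fully contain the Gaussian.
    """
    grid = _gaussian_grid(spec, n, h)
    phi = spec.orientation
    for _ in range(spec.order_parallel):
        grid = _directional_derivative(grid, phi, h, perpendicular=False)
    for _ in range(spec.order_perp):
        grid = _directional_derivative(grid, phi, h, perpendicular=True)
    sp = np.sqrt(spec.scale) * spec.sigma_parallel
    so = np.sqrt(spec.scale) * spec.sigma_perp
    grid = grid * sp**spec.order_parallel * so**spec.order_perp
    return grid * h * h


def sample_kernel(
    spec: SpatialKernelSpec,
    supersample_resolution: int = 81,
    size: int = 9,
    extent: float | None = None,
) -> np.ndarray:
    """Sample one kernel and area-downsample it to a compact mask.

    The continuous kernel is sampled on a ``supersample_resolution`` square
    grid covering ``extent`` px (default: ``size`` px, i.e. unit-pixel cells
    of the output mask), then block-averaged down to ``size`` x ``size``.
    After downsampling the mask is discretely normalized: zeroth-order
    kernels are rescaled to unit sum, derivative kernels have their DC
    component removed so they sum exactly to zero (large-scale kernels are
    truncated by the finite support, which otherwise leaves a boundary
    residue).

    Parameters
    ----------
    supersample_resolution:
        Odd multiple of ``size``; samples per side of the fine grid.
    size:
        Side length of the output mask (odd).
    extent:
        Physical width in px covered by the mask; defaults to ``size``.
    """
    if size % 2 == 0:
        raise ValueError("mask size must be odd")
    n = int(supersample_resolution)
    if n < size or n % 2 == 0 or n % size != 0:
        raise ValueError(
            "supersample_resolution must be an odd multiple of the mask size"
        )
    if extent is None:
        extent = float(size)
    h = extent / n
    fine = sample_kernel_highres(spec, n, h)
    f = n // size
    coarse = fine.reshape(size, f, size, f).sum(axis=(1, 3))
    if spec.order == 0:
        total = coarse.sum()
        if total <= 0:
            raise ValueError("degenerate kernel: non-positive mass")
        coarse = coarse / total
    else:
        coarse = coarse - coarse.mean()
    return coarse


@dataclass
class KernelBank:
    """An ordered collection of compact spatial kernels and their specs."""

    kernels: np.ndarray  # (N, size, size)
    specs: list[SpatialKernelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.ndim != 3:
            raise ValueError("kernels must be a (N, size, size) array")
        if len(self.specs) != self.kernels.shape[0]:
            raise ValueError("specs and kernels length mismatch")

    def __len__(self) -> int:
        return self.kernels.shape[0]

    def __iter__(self):
        return zip(self.specs, self.kernels)

    @property
    def size(self) -> int:
        return self.kernels.shape[1]

    def save(self, path) -> None:
        """Write the bank to HDF5 (`kernels` dataset + JSON spec attribute)."""
        import h5py

        with h5py.File(path, "w") as f:
            dset = f.create_dataset("kernels", data=self.kernels)
            dset.attrs["specs"] = json.dumps([asdict(s) for s in self.specs])

    @classmethod
    def load(cls, path) -> "KernelBank":
        import h5py

        with h5py.File(path, "r") as f:
            kernels = f["kernels"][()]
            specs = [
                SpatialKernelSpec(**d)
                for d in json.loads(f["kernels"].attrs["specs"])
            ]
        return cls(kernels=kernels, specs=specs)


def bank_specs(
    orientations: int = 4,
    scales: int = 4,
    skews: int = 3,
    derivative_set: Sequence[tuple[int, int]] = DEFAULT_DERIVATIVE_SET,
    sigma_base: float = 1.0,
) -> list[SpatialKernelSpec]:
    """Cartesian parameter grid behind :func:`build_bank`.

    Orientations are linearly sampled on [0, pi); scales are the geometric
    series sigma_base * 2^k; skews are eigenvalue ratios lambda_perp /
    lambda_par on the geometric grid {1, 1/2, 1/4, ...}.
    """
    if min(orientations, scales, skews) < 1:
        raise ValueError("counts must be >= 1")
    for m1, m2 in derivative_set:
        if m1 + m2 > 2:
            raise ValueError("derivative orders above 2 are unsupported")
    phis = np.linspace(0.0, np.pi, orientations, endpoint=False)
    sigs = sigma_base * 2.0 ** np.arange(scales)
    ratios = 2.0 ** -np.arange(skews)
    specs = []
    for phi in phis:
        for sig in sigs:
            for ratio in ratios:
                for m1, m2 in derivative_set:
                    specs.append(
                        SpatialKernelSpec(
                            orientation=float(phi),
                            sigma_parallel=float(sig),
                            sigma_perp=float(sig * np.sqrt(ratio)),
                            order_parallel=int(m1),
                            order_perp=int(m2),
                        )
                    )
    return specs


def build_bank(
    orientations: int = 4,
    scales: int = 4,
    skews: int = 3,
    derivative_set: Sequence[tuple[int, int]] = DEFAULT_DERIVATIVE_SET,
    seed: int = 0,
    size: int = 9,
    supersample_resolution: int = 81,
    sigma_base: float = 1.0,
) -> KernelBank:
    """Assemble the kernel bank over the Cartesian parameter grid.

    The default configuration (4 orientations x 4 scales x 3 skews x 3
    derivative configurations) yields exactly 144 kernels of 9x9 px.  The
    construction is deterministic; ``seed`` is recorded for provenance only.
    """
    specs = bank_specs(orientations, scales, skews, derivative_set, sigma_base)
    kernels = np.stack(
        [sample_kernel(s, supersample_resolution, size) for s in specs]
    )
    bank = KernelBank(kernels=kernels, specs=specs)
    bank.seed = int(seed)
    return bank
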