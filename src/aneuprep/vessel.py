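"""Multi-scale Hessian vessel enhancement (Frangi vesselness).

TOF-MRA renders flowing blood hyperintense, so cerebral arteries appear
as bright tubes on a dark background.  At a scale σ the eigenvalues of
the σ²-normalised Gaussian-derivative Hessian describe local shape: a
bright tube has one near-zero eigenvalue along its axis and two large
negative ones across it.  The Frangi measure turns the sorted eigenvalues
|λ1| ≤ |λ2| ≤ |λ3| into a tubularity score in [0, 1],

    V = (1 − exp(−R_A²/2α²)) · exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),

with the plate/line ratio R_A = |λ2|/|λ3|, the blobness R_B =
|λ1|/√(|λ2 λ3|) and the structureness S = √(λ1²+λ2²+λ3²); voxels with
λ2 > 0 or λ3 > 0 (dark structures) score 0.  Responses are computed at
several σ in mm and the voxelwise maximum across scales is kept so both
small and large calibres respond.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import ParameterError, Volume3D, logger

__all__ = [
    "ScaleSpaceParams",
    "HessianEigenField",
    "VesselnessResponse",
    "gaussian_prefilter",
    "hessian_eigenvalues",
    "frangi_response",
    "multiscale_vesselness",
]

#: sentinel for "choose c as half the maximum Hessian Frobenius norm"
C_AUTO = "auto"


@dataclass
class ScaleSpaceParams:
    """Parameters of the multi-scale Hessian filter.

    ``scales_mm`` are the Gaussian derivative scales σ in mm; defaults
    cover intracranial vessel calibres from perforator-sized to the
    basilar artery.  ``c`` may be a positive number or ``"auto"``,
    meaning half of the maximum Hessian Frobenius norm over the volume
    (the original Frangi recipe for the structureness weight).
    """

    scales_mm: tuple = (0.5, 1.0, 2.0, 3.0)
    prefilter_sigma_mm: float = 0.5
    alpha: float = 0.5
    beta: float = 0.5
    c: object = C_AUTO

    def __post_init__(self):
        self.scales_mm = tuple(float(s) for s in self.scales_mm)
        if len(self.scales_mm) == 0:
            raise ParameterError("scales_mm must be non-empty")
        if any(s <= 0 for s in self.scales_mm):
            raise ParameterError("scales must be strictly positive")
        if any(b <= a for a, b in zip(self.scales_mm, self.scales_mm[1:])):
            raise ParameterError("scales must be strictly increasing")
        if self.alpha <= 0 or self.beta <= 0:
            raise ParameterError("alpha and beta must be > 0")
        if self.prefilter_sigma_mm < 0:
            raise ParameterError("prefilter sigma must be >= 0")
        if self.c != C_AUTO and (not np.isscalar(self.c) or float(self.c) <= 0):
            raise ParameterError("c must be a positive number or 'auto'")


@dataclass
class HessianEigenField:
    """Eigenvalues of the σ²-normalised Hessian, |λ1| ≤ |λ2| ≤ |λ3| voxelwise."""

    lam1: np.ndarray
    lam2: np.ndarray
    lam3: np.ndarray
    sigma_mm: float


@dataclass
class VesselnessResponse(Volume3D):
    """Per-voxel tubularity in [0, 1] on a :class:`Volume3D` grid."""

    def __post_init__(self):
        super().__post_init__()
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ParameterError(f"vesselness must lie in [0,1], got range [{lo}, {hi}]")


def _sigma_voxels(sigma_mm: float, spacing) -> tuple:
    return tuple(sigma_mm / s for s in spacing)


def gaussian_prefilter(vol: Volume3D, sigma_mm: float) -> Volume3D:
    """Gaussian smoothing with σ given in mm, anisotropy-aware.

    σ is converted per axis to voxel units (σ_mm / spacing); reflect
    boundary handling.  ``sigma_mm = 0`` returns the input unchanged.
    """
    if sigma_mm < 0:
        raise ParameterError(f"sigma_mm must be >= 0, got {sigma_mm}")
    if sigma_mm == 0:
        return vol
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=np.float64),
        sigma=_sigma_voxels(sigma_mm, vol.spacing),
        mode="reflect",
    )
    return vol.with_data(out)


def _gauss_kernel1d(sigma: float, order: int, truncate: float = 4.0) -> np.ndarray:
    """Truncated Gaussian-derivative kernel with exact discrete moments.

    The raw truncated kernels do not annihilate constants exactly, which
    would leak spurious curvature into flat regions; the corrections
    below make the order-2 kernel zero-sum with unit response to x²/2
    and give the order-1 kernel unit response to x.
    """
    radius = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    if order == 0:
        return g
    if order == 1:
        k = -(x / sigma**2) * g  # antisymmetric: zero-sum exactly
        return k / abs(np.sum(-x * k))
    if order == 2:
        k = ((x**2 - sigma**2) / sigma**4) * g
        k -= k.sum() / k.size  # annihilate constants exactly
        return k * (2.0 / np.sum(k * x**2))
    raise ParameterError(f"unsupported derivative order {order}")


def hessian_eigenvalues(vol: Volume3D, sigma_mm: float) -> HessianEigenField:
    """Eigenvalues of the σ²-scaled Gaussian-derivative Hessian.

    Second derivatives are taken per axis in mm⁻² (derivative filters act
    on voxel indices and are divided by the spacing once per derivative
    order), then multiplied by σ² for scale-space comparability.
    Eigenvalues are sorted by increasing magnitude at every voxel.
    """
    if sigma_mm <= 0:
        raise ParameterError(f"sigma_mm must be > 0, got {sigma_mm}")
    data = np.asarray(vol.data, dtype=np.float64)
    sig_vox = _sigma_voxels(sigma_mm, vol.spacing)
    sp = vol.spacing

    def deriv(orders):
        out = data
        for ax, (sv, o) in enumerate(zip(sig_vox, orders)):
            kernel = _gauss_kernel1d(sv, o)
            out = ndimage.correlate1d(out, kernel, axis=ax, mode="reflect")
            if o:
                out = out / sp[ax] ** o
        return out

    norm = sigma_mm**2
    H = np.empty(data.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            orders = [0, 0, 0]
            orders[i] += 1
            orders[j] += 1
            H[..., i, j] = H[..., j, i] = norm * deriv(tuple(orders))

    lam = np.linalg.eigvalsh(H)  # ascending by value
    order = np.argsort(np.abs(lam), axis=-1)
    lam = np.take_along_axis(lam, order, axis=-1)
    return HessianEigenField(
        lam1=lam[..., 0], lam2=lam[..., 1], lam3=lam[..., 2], sigma_mm=float(sigma_mm)
    )


def frangi_response(
    eigs: HessianEigenField,
    params: ScaleSpaceParams,
    spacing=(1.0, 1.0, 1.0),
    origin_offset=(0, 0, 0),
) -> VesselnessResponse:
    """Frangi tubularity from a Hessian eigenvalue field (bright tubes only).

    Voxels with λ2 > 0 or λ3 > 0 are suppressed, matching the bright-vessel
    contrast of TOF-MRA.  Where λ3 = 0 there is no structure and the
    response is 0; a small positive floor protects the square root in R_B.
    """
    l1, l2, l3 = eigs.lam1, eigs.lam2, eigs.lam3
    a1, a2, a3 = np.abs(l1), np.abs(l2), np.abs(l3)
    S2 = l1**2 + l2**2 + l3**2

    if params.c == C_AUTO:
        smax = float(np.sqrt(S2.max()))
        c = 0.5 * smax if smax > 0 else 1.0
    else:
        c = float(params.c)

    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        Ra2 = np.where(a3 > 0, (a2 / np.maximum(a3, eps)) ** 2, 0.0)
        Rb2 = a1**2 / np.maximum(a2 * a3, eps)
    V = (
        (1.0 - np.exp(-Ra2 / (2 * params.alpha**2)))
        * np.exp(-Rb2 / (2 * params.beta**2))
        * (1.0 - np.exp(-S2 / (2 * c**2)))
    )
    V = np.where((l2 > 0) | (l3 > 0) | (a3 <= eps), 0.0, V)
    return VesselnessResponse(
        data=np.clip(V, 0.0, 1.0), spacing=spacing, origin_offset=origin_offset
    )


def multiscale_vesselness(vol: Volume3D, params: ScaleSpaceParams | None = None) -> VesselnessResponse:
    """Prefilter once, evaluate Frangi at each scale, keep the voxelwise max.

    The maximum over scales lets thin and thick vessels respond at their
    matched σ; adding a scale can therefore never decrease the response.
    """
    params = params or ScaleSpaceParams()
    smoothed = gaussian_prefilter(vol, params.prefilter_sigma_mm)
    best = None
    for sigma in params.scales_mm:
        eigs = hessian_eigenvalues(smoothed, sigma)
        resp = frangi_response(eigs, params, spacing=vol.spacing, origin_offset=vol.origin_offset)
        best = resp.data if best is None else np.maximum(best, resp.data)
        logger.debug("vesselness scale %.2f mm: max response %.4f", sigma, resp.data.max())
    return VesselnessResponse(data=best, spacing=vol.spacing, origin_offset=vol.origin_offset)
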