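"""Synthetic TOF-MRA phantoms: bright tubes, saccular aneurysms, noise.

Deterministic ground-truth generator used throughout the test suite.
Vessels are tubes around polylines with a Gaussian radial intensity
profile (peak · exp(−d²/2r²), d = distance to the centreline in mm) on
a dark background; saccular aneurysms are spheres attached tangent to a
tube surface; additive noise is seeded and reproducible.  Presets
emulate the aneurysm-size regimes of public and clinical cohorts
(median maximum diameters ≈ 3.6 mm and ≈ 9.35 mm respectively), and
random "network" phantoms span the cranial volume along every axis the
way the intracranial vascular tree spans an angiography slab — which is
what makes the minimum vessel bounding box a safe aneurysm ROI.

Limits: no MR flow physics, no intensity inhomogeneity, no intra-
aneurysmal dark signal; fusiform dilations are available as a local
radius bulge on a tube but are not used by the default presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import BinaryMask3D, ParameterError, Volume3D

__all__ = [
    "Tube",
    "Aneurysm",
    "Blob",
    "PhantomSpec",
    "PhantomCase",
    "make_tube",
    "attach_aneurysm",
    "make_case",
    "tube_surface_point",
    "adam_like",
    "renji_like",
    "tube_only",
    "random_network_spec",
]

#: polyline sampling step as a fraction of the smallest voxel spacing
_SAMPLE_STEP_FRAC = 0.25


@dataclass(frozen=True)
class Tube:
    """A vessel: polyline control points (mm), radius (mm), peak intensity.

    ``bulge = (s0_mm, width_mm, factor)`` optionally dilates the radius
    around arclength s0 by ``factor`` with Gaussian falloff (a fusiform
    segment); ``None`` keeps the radius constant.
    """

    points_mm: tuple
    radius_mm: float
    peak: float = 1.0
    bulge: tuple | None = None


@dataclass(frozen=True)
class Aneurysm:
    """A saccular aneurysm: attachment point on a tube surface, diameter, peak."""

    attachment_mm: tuple
    diameter_mm: float
    peak: float = 1.0


@dataclass(frozen=True)
class Blob:
    """A far-field bright sphere not belonging to any ground-truth mask."""

    center_mm: tuple
    diameter_mm: float
    peak: float = 1.0


@dataclass
class PhantomSpec:
    shape: tuple = (48, 48, 48)
    spacing: tuple = (1.0, 1.0, 1.0)
    tubes: tuple = ()
    aneurysms: tuple = ()
    noise_blobs: tuple = ()
    background_intensity: float = 0.1
    noise_sigma: float = 0.05
    noise_model: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.tubes = tuple(self.tubes)
        self.aneurysms = tuple(self.aneurysms)
        self.noise_blobs = tuple(self.noise_blobs)
        if self.noise_model not in ("gaussian", "rician"):
            raise ParameterError(f"noise_model must be 'gaussian' or 'rician', got {self.noise_model!r}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def extent_mm(self) -> tuple:
        """Coordinates of the last voxel centre along each axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))


@dataclass
class PhantomCase:
    image: Volume3D
    vessel_mask: BinaryMask3D
    aneurysm_mask: BinaryMask3D
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Geometry


def _voxel_centers_mm(shape, spacing) -> np.ndarray:
    grids = np.indices(shape).reshape(3, -1).T
    return grids * np.asarray(spacing)


def _sample_polyline(points_mm: np.ndarray, step_mm: float):
    """Dense arclength samples along a polyline; returns (points, arclengths)."""
    pts, arcs = [], []
    s = 0.0
    for a, b in zip(points_mm[:-1], points_mm[1:]):
        seg = np.linalg.norm(b - a)
        n = max(2, int(math.ceil(seg / step_mm)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        pts.append(a + ts[:, None] * (b - a))
        arcs.append(s + ts * seg)
        s += seg
    return np.vstack(pts), np.concatenate(arcs)


def _tube_radii(tube: Tube, arcs: np.ndarray) -> np.ndarray:
    r = np.full(arcs.shape, tube.radius_mm)
    if tube.bulge is not None:
        s0, width, factor = tube.bulge
        r = r * (1.0 + (factor - 1.0) * np.exp(-((arcs - s0) ** 2) / (2.0 * width**2)))
    return r


def _validate_tube(tube: Tube, spec_shape, spacing):
    pts = np.asarray(tube.points_mm, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ParameterError("a tube needs >= 2 control points of dimension 3")
    if np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() == 0:
        raise ParameterError("zero-length polyline")
    if tube.radius_mm <= 0:
        raise ParameterError("tube radius must be > 0")
    ext = [(n - 1) * s for n, s in zip(spec_shape, spacing)]
    if (pts < -1e-9).any() or (pts > np.asarray(ext) + 1e-9).any():
        raise ParameterError(f"polyline leaves the volume bounds {ext}")
    return pts


def _tube_distance_field(tube: Tube, shape, spacing):
    """Per-voxel distance to the centreline (mm) and local radius."""
    pts = _validate_tube(tube, shape, spacing)
    step = _SAMPLE_STEP_FRAC * min(spacing)
    samples, arcs = _sample_polyline(pts, step)
    radii = _tube_radii(tube, arcs)
    centers = _voxel_centers_mm(shape, spacing)
    dist, idx = cKDTree(samples).query(centers, k=1)
    return (
        dist.reshape(shape),
        radii[idx].reshape(shape),
        samples,
        arcs,
    )


def make_tube(shape, spacing, tube: Tube):
    """Rasterise one tube: Gaussian-profile intensity grid and binary mask.

    Intensity is ``peak · exp(−d²/2r²)`` with d the mm distance to the
    centreline; the mask is ``d ≤ r`` (including hemispherical end caps
    of the nominal radius beyond the polyline ends).
    """
    dist, radius, _, _ = _tube_distance_field(tube, shape, spacing)
    intensity = tube.peak * np.exp(-(dist**2) / (2.0 * radius**2))
    return intensity, dist <= radius


def tube_surface_point(tube: Tube, frac: float, direction) -> tuple:
    """A point on the tube surface: axis point at arclength fraction
    ``frac`` plus ``radius`` along the (normalised, axis-perpendicular)
    ``direction``.  Convenience for placing aneurysm attachments."""
    pts = np.asarray(tube.points_mm, dtype=np.float64)
    total = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if total == 0:
        raise ParameterError("zero-length polyline")
    samples, arcs = _sample_polyline(pts, max(total / 1000.0, 1e-6))
    axis_pt = samples[np.argmin(np.abs(arcs - frac * total))]
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    return tuple(axis_pt + tube.radius_mm * d)


def attach_aneurysm(shape, spacing, tubes, aneurysm: Aneurysm, vessel_mask=None):
    """Rasterise a saccular aneurysm tangent to a tube at its attachment.

    The attachment must lie on some tube's surface (within half a voxel);
    the sphere centre sits one aneurysm-radius outward along the radial
    direction, so sphere and tube touch at the attachment.  The returned
    mask excludes tube interiors, so vessel and aneurysm ground truths
    stay disjoint while adjacent.
    """
    if aneurysm.diameter_mm < min(spacing):
        raise ParameterError(
            f"aneurysm diameter {aneurysm.diameter_mm} mm is below one voxel "
            f"(min spacing {min(spacing)} mm)"
        )
    att = np.asarray(aneurysm.attachment_mm, dtype=np.float64)
    tol = 0.5 * min(spacing)
    host = None
    if vessel_mask is None:
        vessel_mask = np.zeros(shape, dtype=bool)
        for tube in tubes:
            _, m = make_tube(shape, spacing, tube)
            vessel_mask |= m
    for tube in tubes:
        pts = _validate_tube(tube, shape, spacing)
        samples, arcs = _sample_polyline(pts, _SAMPLE_STEP_FRAC * min(spacing))
        radii = _tube_radii(tube, arcs)
        d, i = cKDTree(samples).query(att, k=1)
        if abs(d - radii[i]) <= tol and d > 0:
            host = (tube, samples[i])
            break
    if host is None:
        raise ParameterError(f"attachment {tuple(att)} does not lie on any tube surface")

    _, nearest = host
    outward = att - nearest
    outward /= np.linalg.norm(outward)
    R = aneurysm.diameter_mm / 2.0
    center = att + outward * R

    rho = np.linalg.norm(
        _voxel_centers_mm(shape, spacing) - center, axis=1
    ).reshape(shape)
    intensity = aneurysm.peak * np.exp(-(rho**2) / (2.0 * R**2))
    mask = (rho <= R) & ~vessel_mask
    return intensity, mask


def _blob_grid(shape, spacing, blob: Blob):
    rho = np.linalg.norm(
        _voxel_centers_mm(shape, spacing) - np.asarray(blob.center_mm), axis=1
    ).reshape(shape)
    R = blob.diameter_mm / 2.0
    return blob.peak * np.exp(-(rho**2) / (2.0 * R**2)), rho <= R


def make_case(spec: PhantomSpec) -> PhantomCase:
    """Compose tubes, aneurysms, blobs, background and seeded noise.

    The noiseless image is the voxelwise maximum of the background and
    every structure's intensity profile; every ground-truth vessel voxel
    therefore sits strictly above background whenever
    ``peak·e^{−1/2} > background``.  Identical specs (same seed) give
    bit-identical cases.
    """
    shape, spacing = spec.shape, spec.spacing
    image = np.full(shape, float(spec.background_intensity))
    vessel = np.zeros(shape, dtype=bool)
    for tube in spec.tubes:
        inten, mask = make_tube(shape, spacing, tube)
        image = np.maximum(image, inten)
        vessel |= mask
    aneurysm = np.zeros(shape, dtype=bool)
    for an in spec.aneurysms:
        inten, mask = attach_aneurysm(shape, spacing, spec.tubes, an, vessel_mask=vessel)
        image = np.maximum(image, inten)
        aneurysm |= mask
    for blob in spec.noise_blobs:
        inten, _ = _blob_grid(shape, spacing, blob)
        image = np.maximum(image, inten)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            image = image + spec.noise_sigma * rng.standard_normal(shape)
        else:  # rician: magnitude of a complex signal with Gaussian channels
            n1 = spec.noise_sigma * rng.standard_normal(shape)
            n2 = spec.noise_sigma * rng.standard_normal(shape)
            image = np.sqrt((image + n1) ** 2 + n2**2)

    return PhantomCase(
        image=Volume3D(data=image, spacing=spacing),
        vessel_mask=BinaryMask3D(data=vessel, spacing=spacing),
        aneurysm_mask=BinaryMask3D(data=aneurysm, spacing=spacing),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Presets


def _axis_tube(axis: int, extent, through_mm, radius: float, peak: float = 1.0) -> Tube:
    """A tube spanning the full volume along ``axis`` through ``through_mm``."""
    a = list(through_mm)
    b = list(through_mm)
    a[axis] = 0.0
    b[axis] = extent[axis]
    return Tube(points_mm=(tuple(a), tuple(b)), radius_mm=radius, peak=peak)


def tube_only(seed: int = 0) -> PhantomSpec:
    """One straight 2 mm-radius tube spanning z on a 48 mm isotropic grid."""
    shape, spacing = (48, 48, 48), (1.0, 1.0, 1.0)
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))
    tube = _axis_tube(2, ext, (ext[0] / 2, ext[1] / 2, 0.0), radius=2.0)
    return PhantomSpec(shape=shape, spacing=spacing, tubes=(tube,), seed=seed)


def adam_like(seed: int = 0) -> PhantomSpec:
    """Small-aneurysm regime: diameters {1.0, 3.6, 15.9} mm at 0.5 mm spacing.

    Diameters cover the minimum, median and maximum maximum-diameters of
    the public challenge cohort this emulates.
    """
    shape, spacing = (64, 64, 64), (0.5, 0.5, 0.5)
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))  # 31.5 mm
    r = 2.0
    tube = _axis_tube(2, ext, (8.0, 16.0, 0.0), radius=r)
    aneurysms = (
        Aneurysm(attachment_mm=(8.0 - r, 16.0, 8.0), diameter_mm=1.0),
        Aneurysm(attachment_mm=(8.0, 16.0 + r, 24.0), diameter_mm=3.6),
        Aneurysm(attachment_mm=(8.0 + r, 16.0, 15.75), diameter_mm=15.9),
    )
    return PhantomSpec(shape=shape, spacing=spacing, tubes=(tube,), aneurysms=aneurysms, seed=seed)


def renji_like(seed: int = 0) -> PhantomSpec:
    """Large-aneurysm clinical regime: diameters {2.0, 9.35, 18.0} mm."""
    shape, spacing = (64, 64, 64), (0.8, 0.8, 0.8)
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))  # 50.4 mm
    r = 2.5
    tube = _axis_tube(2, ext, (12.0, 25.0, 0.0), radius=r)
    aneurysms = (
        Aneurysm(attachment_mm=(12.0 - r, 25.0, 10.0), diameter_mm=2.0),
        Aneurysm(attachment_mm=(12.0, 25.0 + r, 40.0), diameter_mm=9.35),
        Aneurysm(attachment_mm=(12.0 + r, 25.0, 25.2), diameter_mm=18.0),
    )
    return PhantomSpec(shape=shape, spacing=spacing, tubes=(tube,), aneurysms=aneurysms, seed=seed)


def random_network_spec(
    seed: int,
    with_blob: bool = True,
    contrast_over_sigma: float = 18.0,
) -> PhantomSpec:
    """A seeded vascular-network phantom with one attached aneurysm.

    Three thick "trunk" tubes (radii ~ U(2, 3) mm), one spanning the
    full volume along each axis, emulate the way the major intracranial
    arteries traverse an angiography slab; one or two thin interior
    connector tubes (radii ~ U(0.5, 2) mm) link trunk axes, so tube
    radii across phantoms span 0.5–3 mm.  Trunks are mutually offset so
    they never cross: curvature-based vesselness is suppressed at
    junctions, and a trunk split at a crossing could fall below the
    component-size suppression floor.  Each trunk alone comfortably
    exceeds that floor, which together with the full axis spans makes
    the vessel bounding box cover the whole ground truth by geometry.

    One saccular aneurysm (diameter log-uniform over 1–16 mm) attaches
    to the z trunk, always inside the volume; an optional far-field
    bright blob well under 500 voxels sits near a corner.
    ``contrast_over_sigma`` fixes the tube-to-background contrast in
    units of the noise SD (kept well above the ≥3σ detectability
    regime).
    """
    rng = np.random.default_rng(seed)
    diameter = float(10 ** rng.uniform(0.0, math.log10(16.0)))
    if diameter > 8.0:
        shape, spacing_val = (64, 64, 64), 1.0
    elif diameter > 4.0:
        shape, spacing_val = (48, 48, 48), 1.0
    else:
        # keep the aneurysm >= 2 voxels across so its mask is never empty
        options = [s for s in (0.5, 0.6, 0.8, 1.0) if s <= diameter / 2.0] or [0.5]
        shape, spacing_val = (48, 48, 48), float(rng.choice(options))
    spacing = (spacing_val,) * 3
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))

    def jitter(frac):
        return float((frac + rng.uniform(-0.03, 0.03)) * 1.0)

    trunk_r = rng.uniform(2.0, 3.0, size=3)
    # transverse positions chosen so trunk axes stay > r_i + r_j apart
    pos_x = (0.0, jitter(0.25) * ext[1], jitter(0.25) * ext[2])
    pos_y = (jitter(0.75) * ext[0], 0.0, jitter(0.75) * ext[2])
    hub = (jitter(0.5) * ext[0], jitter(0.5) * ext[1], 0.0)
    trunks = (
        _axis_tube(0, ext, pos_x, radius=float(trunk_r[0])),
        _axis_tube(1, ext, pos_y, radius=float(trunk_r[1])),
        _axis_tube(2, ext, hub, radius=float(trunk_r[2])),
    )
    # thin interior connectors between trunk axes
    connectors = []
    for _ in range(int(rng.integers(1, 3))):
        a = (float(rng.uniform(0.3, 0.7) * ext[0]), pos_x[1], pos_x[2])
        b = (hub[0], hub[1], float(rng.uniform(0.3, 0.7) * ext[2]))
        connectors.append(
            Tube(points_mm=(a, b), radius_mm=float(rng.uniform(0.5, 2.0)))
        )
    tubes = trunks + tuple(connectors)

    # attach to the z trunk, pointing toward whichever x side has more room
    rz = float(trunk_r[2])
    R = diameter / 2.0
    sign = 1.0 if hub[0] <= ext[0] / 2 else -1.0
    z_att = float(rng.uniform(0.3, 0.7) * ext[2])
    z_att = float(np.clip(z_att, R + 1.0, ext[2] - R - 1.0))
    attachment = (hub[0] + sign * rz, hub[1], z_att)
    aneurysms = (Aneurysm(attachment_mm=attachment, diameter_mm=diameter),)

    blobs = ()
    if with_blob:
        corner = (0.92 * ext[0], 0.08 * ext[1], 0.92 * ext[2])
        blobs = (Blob(center_mm=corner, diameter_mm=3.0 * spacing_val, peak=1.0),)

    background = 0.1
    peak = 1.0
    sigma = (peak - background) / contrast_over_sigma
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        tubes=tubes,
        aneurysms=aneurysms,
        noise_blobs=blobs,
        background_intensity=background,
        noise_sigma=sigma,
        seed=seed,
    )
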