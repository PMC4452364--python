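"""Digital sphere-phantom simulator.

Emulates PET acquisitions of a NEMA-IEC-style body phantom: nine fillable
spheres (internal diameters 6.5-57.4 mm) in a warm background, imaged at a
grid of target-to-background ratios (TBR) and emission scan durations (ESD),
blurred by the scanner point spread function, degraded by count-statistics
noise and post-smoothed with a transaxial Gaussian filter.

The simulation is deliberately image-domain only: scanner resolution is an
isotropic 3D Gaussian PSF, noise is additive Gaussian with a variance
proportional to local activity and inversely proportional to scan duration,
and reconstruction is represented solely by its user-facing parameters
(transaxial filter FWHM, iteration number, and inert extras).  Sinogram-level
physics (scatter, attenuation, randoms, TOF) is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Internal diameters (mm) of the nine phantom spheres.
DEFAULT_SPHERE_IDS = (6.5, 8.1, 10.0, 13.0, 17.0, 22.0, 28.0, 37.0, 57.4)

#: Nominal target-to-background ratios of the standard acquisition protocol.
DEFAULT_TBRS = (2.5, 4.0, 8.0, 16.0, 25.0, 35.0, 47.0, 55.0, 70.0)

#: Emission scan durations (minutes) of the standard protocol.
DEFAULT_ESDS = (2.0, 3.0, 4.0, 5.0)

#: Background activity concentration (kBq/mL).
DEFAULT_BACKGROUND = 3.0

#: Default scanner intrinsic transverse resolution, FWHM in mm.
DEFAULT_PSF_FWHM = 6.3


@dataclass(frozen=True)
class SphereSpec:
    """Ground-truth geometry of one fillable sphere.

    Parameters
    ----------
    center : 3-tuple of float
        Sphere center in world coordinates, mm.
    internal_diameter : float
        Internal diameter (ID), mm.
    label : str
        Identifier used in measurement tables, defaults to the ID in mm.
    """

    center: tuple[float, float, float]
    internal_diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.internal_diameter <= 0:
            raise ValueError("sphere internal_diameter must be > 0")
        if not self.label:
            object.__setattr__(self, "label", f"{self.internal_diameter:g}mm")

    @property
    def radius(self) -> float:
        return self.internal_diameter / 2.0

    @property
    def true_area(self) -> float:
        """Maximal cross-sectional area, mm^2 (the equatorial disk)."""
        return math.pi * self.radius**2

    @property
    def true_volume(self) -> float:
        """Sphere volume in mL (1 mL = 1000 mm^3)."""
        return (4.0 / 3.0) * math.pi * self.radius**3 / 1000.0


def _default_sphere_layout() -> tuple[SphereSpec, ...]:
    """Nine spheres: a coplanar ring of six plus three at the bottom.

    The six standard spheres (ID 10-37 mm) sit on a 57.2 mm-radius ring in
    the z = 0 plane; the two micro-spheres and the 57.4 mm sphere sit on a
    row in a lower plane, mimicking the physical phantom's supplemental
    inserts at the bottom of the cavity.
    """
    ring_ids = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    ring_radius = 57.2
    spheres = []
    for k, sphere_id in enumerate(ring_ids):
        angle = math.radians(60.0 * k)
        spheres.append(
            SphereSpec(
                center=(
                    round(ring_radius * math.cos(angle), 6),
                    round(ring_radius * math.sin(angle), 6),
                    0.0,
                ),
                internal_diameter=sphere_id,
            )
        )
    bottom_ids = (6.5, 8.1, 57.4)
    for x, sphere_id in zip((-70.0, 0.0, 70.0), bottom_ids):
        spheres.append(
            SphereSpec(center=(x, -100.0, -49.5), internal_diameter=sphere_id)
        )
    return tuple(spheres)


@dataclass(frozen=True)
class PhantomSpec:
    """A sphere phantom: geometry plus activity concentrations.

    ``tbr_nominal`` is the hot-sphere-to-background activity ratio actually
    put into the phantom; the measured TBR read back from the reconstructed
    image is generally lower because of partial-volume effects.
    """

    spheres: tuple[SphereSpec, ...] = field(default_factory=_default_sphere_layout)
    background_activity: float = DEFAULT_BACKGROUND
    tbr_nominal: float = 8.0

    def __post_init__(self) -> None:
        if self.background_activity <= 0:
            raise ValueError("background_activity must be > 0")
        if self.tbr_nominal < 1:
            raise ValueError("tbr_nominal must be >= 1")
        centers = np.array([s.center for s in self.spheres], dtype=float)
        radii = np.array([s.radius for s in self.spheres], dtype=float)
        for i in range(len(self.spheres)):
            for j in range(i + 1, len(self.spheres)):
                gap = np.linalg.norm(centers[i] - centers[j])
                if gap < radii[i] + radii[j]:
                    raise ValueError(
                        f"spheres {self.spheres[i].label} and "
                        f"{self.spheres[j].label} overlap"
                    )

    def with_tbr(self, tbr: float) -> "PhantomSpec":
        return PhantomSpec(self.spheres, self.background_activity, tbr)

    def sphere(self, label: str) -> SphereSpec:
        for s in self.spheres:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class AcquisitionSpec:
    """One emission acquisition: scanner resolution, duration, noise level.

    Noise is additive Gaussian with per-voxel standard deviation
    ``noise_coeff * sqrt(activity / esd)``, applied after the PSF blur.
    The 1/sqrt(ESD) scaling mimics Poisson counting statistics: doubling the
    scan duration halves the variance.
    """

    psf_fwhm: float = DEFAULT_PSF_FWHM
    esd: float = 5.0
    noise_coeff: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.esd <= 0:
            raise ValueError("esd must be > 0")
        if self.noise_coeff < 0:
            raise ValueError("noise_coeff must be >= 0")


@dataclass(frozen=True)
class ReconSpec:
    """User-facing reconstruction parameters.

    Only the transaxial post-filter FWHM has any effect on the simulated
    image.  The iteration number and the ``extras`` (axial kernel label,
    relaxation, TOF kernel width, voxel dims ...) are carried as covariates
    so that calibration can verify they are not predictors of the threshold.
    """

    transaxial_fwhm: float = 6.0
    em_iterations: int = 32
    extras: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.transaxial_fwhm < 0:
            raise ValueError("transaxial_fwhm must be >= 0")
        if self.em_iterations < 1:
            raise ValueError("em_iterations must be >= 1")


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel geometry of a reconstructed volume.

    ``origin`` is the world coordinate (mm) of the center of voxel (0,0,0);
    axes are ordered (x, y, z) with z the axial direction.
    """

    shape: tuple[int, int, int] = (128, 128, 55)
    voxel_size: tuple[float, float, float] = (2.7, 2.7, 3.3)
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.shape):
            raise ValueError("grid dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.origin is None:
            # center the grid on the world origin
            origin = tuple(
                -(n - 1) / 2.0 * v for n, v in zip(self.shape, self.voxel_size)
            )
            object.__setattr__(self, "origin", origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def world_to_index(self, point: Sequence[float]) -> tuple[int, int, int]:
        """Nearest-voxel index of a world point."""
        return tuple(
            int(round((p - o) / v))
            for p, o, v in zip(point, self.origin, self.voxel_size)
        )

    def contains_sphere(self, sphere: SphereSpec) -> bool:
        lo = [o - v / 2.0 for o, v in zip(self.origin, self.voxel_size)]
        hi = [
            o + (n - 0.5) * v
            for o, n, v in zip(self.origin, self.shape, self.voxel_size)
        ]
        return all(
            lo[a] <= sphere.center[a] - sphere.radius
            and sphere.center[a] + sphere.radius <= hi[a]
            for a in range(3)
        )


@dataclass
class ImageVolume:
    """A 3D intensity grid (kBq/mL-equivalent) with voxel spacing in mm."""

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3 or any(n < 1 for n in self.intensities.shape):
            raise ValueError("intensities must be a 3D grid")
        if self.origin is None:
            self.origin = tuple(
                -(n - 1) / 2.0 * v
                for n, v in zip(self.intensities.shape, self.voxel_size)
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(self.intensities.shape, self.voxel_size, self.origin)

    @property
    def pixel_area(self) -> float:
        """Transaxial pixel area, mm^2."""
        return self.voxel_size[0] * self.voxel_size[1]

    def slice_index_at(self, z_world: float) -> int:
        """Index of the transaxial slice whose plane is closest to z_world."""
        k = int(round((z_world - self.origin[2]) / self.voxel_size[2]))
        return min(max(k, 0), self.intensities.shape[2] - 1)

    def transaxial_slice(self, index: int) -> np.ndarray:
        return self.intensities[:, :, index]

    def copy_with(self, intensities: np.ndarray) -> "ImageVolume":
        return ImageVolume(intensities, self.voxel_size, self.origin)


def build_activity_map(
    phantom: PhantomSpec, grid: VoxelGrid | None = None
) -> ImageVolume:
    """Rasterize the phantom into a noiseless, unblurred activity volume.

    Voxels whose center lies inside a sphere get the hot activity
    ``tbr_nominal * background_activity``; all other voxels get the
    background activity.  Rasterization is by voxel-center membership with
    no anti-aliasing.

    Raises
    ------
    ValueError
        If a sphere does not fit inside the grid (named in the message).
    """
    grid = grid or VoxelGrid()
    for sphere in phantom.spheres:
        if not grid.contains_sphere(sphere):
            raise ValueError(f"sphere {sphere.label} does not fit inside the grid")

    data = np.full(grid.shape, phantom.background_activity, dtype=float)
    hot = phantom.tbr_nominal * phantom.background_activity
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    for sphere in phantom.spheres:
        cx, cy, cz = sphere.center
        # restrict to the sphere's bounding box for speed
        ix = np.flatnonzero(np.abs(xs - cx) <= sphere.radius)
        iy = np.flatnonzero(np.abs(ys - cy) <= sphere.radius)
        iz = np.flatnonzero(np.abs(zs - cz) <= sphere.radius)
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            continue
        dx2 = (xs[ix] - cx) ** 2
        dy2 = (ys[iy] - cy) ** 2
        dz2 = (zs[iz] - cz) ** 2
        inside = (
            dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
            <= sphere.radius**2
        )
        sub = data[np.ix_(ix, iy, iz)]
        sub[inside] = hot
        data[np.ix_(ix, iy, iz)] = sub
    return ImageVolume(data, grid.voxel_size, grid.origin)


def simulate_scan(truth: ImageVolume, acq: AcquisitionSpec) -> ImageVolume:
    """Apply the scanner PSF and count-statistics noise to a truth volume.

    The truth is convolved with an isotropic 3D Gaussian of FWHM
    ``acq.psf_fwhm``; zero-mean Gaussian noise with per-voxel SD
    ``noise_coeff * sqrt(max(blurred, 0) / esd)`` is then added.  Seeded and
    bit-reproducible.
    """
    if acq.psf_fwhm > 0:
        sigma_vox = [
            acq.psf_fwhm * FWHM_TO_SIGMA / v for v in truth.voxel_size
        ]
        blurred = ndimage.gaussian_filter(truth.intensities, sigma_vox, mode="nearest")
    else:
        blurred = truth.intensities.copy()
    if acq.noise_coeff > 0:
        rng = np.random.default_rng(acq.seed)
        sd = acq.noise_coeff * np.sqrt(np.maximum(blurred, 0.0) / acq.esd)
        blurred = blurred + rng.standard_normal(blurred.shape) * sd
    return truth.copy_with(blurred)


def apply_transaxial_filter(img: ImageVolume, recon: ReconSpec) -> ImageVolume:
    """Post-reconstruction transaxial Gaussian smoothing.

    Smoothing acts in the transaxial (x, y) plane only, slice by slice,
    with the stated FWHM in mm.  The replicate-edge mode keeps the total
    intensity of each slice conserved to well within 0.1% for volumes whose
    border is (near-)uniform background, as phantom volumes are.
    """
    if recon.transaxial_fwhm == 0:
        return img.copy_with(img.intensities.copy())
    sigma = [
        recon.transaxial_fwhm * FWHM_TO_SIGMA / img.voxel_size[0],
        recon.transaxial_fwhm * FWHM_TO_SIGMA / img.voxel_size[1],
        0.0,
    ]
    smoothed = ndimage.gaussian_filter(img.intensities, sigma, mode="nearest")
    return img.copy_with(smoothed)


@dataclass(frozen=True)
class SimulatedAcquisition:
    """One simulated, filtered volume together with its ground truth."""

    image: ImageVolume
    phantom: PhantomSpec
    acquisition: AcquisitionSpec
    recon: ReconSpec
    tbr_index: int
    esd_index: int
    recon_index: int


def acquisition_seed(
    master_seed: int, tbr_index: int, esd_index: int, recon_index: int
) -> int:
    """Deterministic per-acquisition seed derived from the triple index."""
    ss = np.random.SeedSequence([int(master_seed), tbr_index, esd_index, recon_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_experiment_grid(
    phantom: PhantomSpec,
    tbrs: Sequence[float] = DEFAULT_TBRS,
    esds: Sequence[float] = DEFAULT_ESDS,
    recons: Sequence[ReconSpec] = (ReconSpec(),),
    *,
    psf_fwhm: float = DEFAULT_PSF_FWHM,
    noise_coeff: float = 1.0,
    grid: VoxelGrid | None = None,
    master_seed: int = 0,
) -> Iterator[SimulatedAcquisition]:
    """Simulate the full acquisition/reconstruction protocol grid.

    Yields one simulated, post-filtered volume per (TBR, ESD, recon) triple.
    The standard protocol (9 TBR x 4 ESD, 9 spheres) gives 324 candidate
    sphere-observations per reconstruction.  Each acquisition gets its own
    seed derived from (master_seed, TBR index, ESD index, recon index), so
    the grid is reproducible as a whole and each volume individually.
    """
    grid = grid or VoxelGrid()
    truth_cache: dict[float, ImageVolume] = {}
    for i_t, tbr in enumerate(tbrs):
        if tbr not in truth_cache:
            truth_cache[tbr] = build_activity_map(phantom.with_tbr(tbr), grid)
        truth = truth_cache[tbr]
        for i_e, esd in enumerate(esds):
            for i_r, recon in enumerate(recons):
                seed = acquisition_seed(master_seed, i_t, i_e, i_r)
                acq = AcquisitionSpec(
                    psf_fwhm=psf_fwhm, esd=esd, noise_coeff=noise_coeff, seed=seed
                )
                scan = simulate_scan(truth, acq)
                filtered = apply_transaxial_filter(scan, recon)
                yield SimulatedAcquisition(
                    image=filtered,
                    phantom=phantom.with_tbr(tbr),
                    acquisition=acq,
                    recon=recon,
                    tbr_index=i_t,
                    esd_index=i_e,
                    recon_index=i_r,
                )


def default_background_rois(
    radius_mm: float = 100.0, count: int = 6, z: float = 0.0
) -> tuple[tuple[float, float, float], ...]:
    """Default background ROI centers: a ring interleaved with the spheres.

    ROIs sit at ``radius_mm`` from the phantom axis in the sphere plane,
    rotated 30 degrees from the sphere positions so that a 17 mm ROI never
    touches a sphere.
    """
    centers = []
    for k in range(count):
        angle = math.radians(30.0 + 360.0 / count * k)
        centers.append(
            (
                round(radius_mm * math.cos(angle), 6),
                round(radius_mm * math.sin(angle), 6),
                z,
            )
        )
    return tuple(centers)
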