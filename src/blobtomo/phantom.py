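"""Synthetic phantoms and simulated tilt series.

Generates caveolae-like test objects — solid spheres and hollow shells
(vesicle cross-sections) — and projects them with an *independent* ray-driven
linear-interpolation projector rather than the blob operator used for
reconstruction.  Simulated data therefore never comes from the transpose of
the operator being inverted (no inverse crime), which keeps end-to-end
recovery tests honest.  Additive Gaussian noise models detector noise; all
randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import TiltGeometry, pixel_centers


@dataclass(frozen=True)
class Sphere:
    """Solid ball: ``center`` in centered voxel coordinates (y, z, x)."""

    center: tuple[float, float, float]
    radius: float
    intensity: float = 1.0


@dataclass(frozen=True)
class Shell:
    """Hollow spherical shell of the given outer radius and thickness."""

    center: tuple[float, float, float]
    radius: float
    thickness: float
    intensity: float = 1.0


def _default_objects():
    # small vesicle-scale objects: the reference volume is a thin 8-slice slab,
    # so everything must fit within ±4 along the tilt axis
    return [
        Shell(center=(0.0, -8.0, -10.0), radius=3.5, thickness=1.5, intensity=1.0),
        Shell(center=(0.0, 10.0, 6.0), radius=3.0, thickness=1.2, intensity=1.0),
        Sphere(center=(0.0, -2.0, 14.0), radius=2.5, intensity=1.5),
        Sphere(center=(0.0, 12.0, -12.0), radius=2.0, intensity=1.2),
    ]


@dataclass(frozen=True)
class PhantomSpec:
    """A reproducible synthetic volume description.

    ``dims`` is (n_slices, n_z, n_x) in the package volume convention; object
    coordinates are volume-centered.  The same spec (and seed, for noisy
    simulations) always regenerates identical arrays.
    """

    dims: tuple[int, int, int] = (8, 64, 64)
    objects: tuple = field(default_factory=lambda: tuple(_default_objects()))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "objects", tuple(self.objects))
        if len(self.dims) != 3 or min(self.dims) < 1:
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        # containment is enforced in-plane only: along the tilt axis (y) a
        # volume is a thin section, and clipping spheres that extend past the
        # slab faces is exactly what real ET specimens do
        half = tuple(d / 2.0 for d in self.dims)
        for obj in self.objects:
            if not np.all(np.isfinite([*obj.center, obj.radius, obj.intensity])):
                raise ValueError(f"non-finite parameters in {obj}")
            for c, h, axis in zip(obj.center[1:], half[1:], "zx"):
                if abs(c) + obj.radius > h:
                    raise ValueError(f"{type(obj).__name__} at center {obj.center} with "
                                     f"radius {obj.radius} leaves the volume along {axis}")
            if abs(obj.center[0]) > half[0]:
                raise ValueError(f"{type(obj).__name__} center {obj.center} lies outside "
                                 "the volume along the tilt axis y")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Voxelize the spec's objects on the centered grid; deterministic."""
    ny, nz, nx = spec.dims
    y, z, x = np.meshgrid(pixel_centers(ny), pixel_centers(nz), pixel_centers(nx),
                          indexing="ij")
    vol = np.zeros(spec.dims, dtype=np.float64)
    for obj in spec.objects:
        cy, cz, cx = obj.center
        r = np.sqrt((y - cy) ** 2 + (z - cz) ** 2 + (x - cx) ** 2)
        if isinstance(obj, Shell):
            mask = (r <= obj.radius) & (r >= obj.radius - obj.thickness)
        else:
            mask = r <= obj.radius
        vol[mask] += obj.intensity
    return vol


def simulate_tilt_series(volume: np.ndarray, geom: TiltGeometry,
                         noise_sigma: float = 0.0, seed: int = 0,
                         step: float = 0.5) -> np.ndarray:
    """Project a volume into a (B, n_slices, S) tilt series.

    Ray-driven projector, deliberately different from the blob forward model:
    each detector ray is sampled at ``step`` intervals through the slice plane
    and the volume is bilinearly interpolated (zero outside), then the samples
    are summed times the step.  Gaussian noise of ``noise_sigma`` is added with
    the given seed; ``sigma=0`` is exactly reproducible.
    """
    volume = np.asarray(volume, dtype=np.float64)
    n_slices, n_z, n_x = volume.shape
    S = geom.n_rays
    u = np.arange(S, dtype=np.float64) - geom.detector_origin  # detector coords
    half_diag = 0.5 * float(np.hypot(n_x, n_z)) + 1.0
    n_t = int(np.ceil(2 * half_diag / step)) + 1
    t = -half_diag + step * np.arange(n_t)

    series = np.empty((geom.n_views, n_slices, S), dtype=np.float64)
    for v, theta in enumerate(geom.angles_rad):
        c, s = np.cos(theta), np.sin(theta)
        # sample points of ray u at parameters t, in slice coordinates (x, z)
        x = u[:, None] * c - t[None, :] * s
        z = u[:, None] * s + t[None, :] * c
        ix = x + (n_x - 1) / 2.0
        iz = z + (n_z - 1) / 2.0
        coords = np.stack([iz.ravel(), ix.ravel()])
        for y in range(n_slices):
            samples = ndimage.map_coordinates(volume[y], coords, order=1,
                                              mode="constant", cval=0.0)
            series[v, y] = samples.reshape(S, n_t).sum(axis=1) * step
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sigma, size=series.shape)
    return series


def recon_metrics(recon: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Root-mean-square error and Pearson correlation over all voxels."""
    recon = np.asarray(recon, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if recon.shape != truth.shape:
        raise ValueError(f"shape mismatch: {recon.shape} vs {truth.shape}")
    rmse = float(np.sqrt(np.mean((recon - truth) ** 2)))
    r = float(np.corrcoef(recon.ravel(), truth.ravel())[0, 1])
    return {"rmse": rmse, "pearson_r": r}
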