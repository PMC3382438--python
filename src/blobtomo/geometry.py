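"""Single-axis-tilt projection geometry.

Coordinate conventions used throughout the package:

* Slice-plane coordinates are *volume-centered*: a length-``n`` axis has pixel
  centers at ``j - (n-1)/2`` (half-integers for even ``n``, so that every pixel
  ``(x, z)`` has a distinct point-reflected partner ``(-x, -z)``).
* Detector bins sit at integer positions in the same unit.  The tilt (rotation)
  axis projects to detector *coordinate* 0 for every tilt angle, and detector
  coordinate 0 maps to array index ``(S-1)/2`` (``detector_origin``), i.e. the
  bin centers are symmetric about the projection of the volume center.
* Tilt angles are degrees externally and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Tolerance (degrees) when matching an angle against the negated set; .tlt
#: files carry limited precision so exact equality would be too strict.
ANGLE_MATCH_TOL_DEG = 1e-6


def pixel_centers(n: int) -> np.ndarray:
    """Centered pixel-center coordinates ``{j - (n-1)/2 : j = 0..n-1}``.

    The centers always sum to exactly zero; for even ``n`` they are
    half-integers so no pixel is its own point-reflection partner.
    """
    if n < 1:
        raise ValueError(f"axis length must be >= 1, got {n}")
    return np.arange(n, dtype=np.float64) - (n - 1) / 2.0


def project_point(x, y, theta_deg):
    """Project a slice-plane point onto the detector line of one tilt view.

    Implements the single-axis parallel-beam projection
    ``r = x*cos(theta) + y*sin(theta)`` in detector units.  Accepts scalars or
    arrays (broadcast).  Two exact sign symmetries follow directly and are the
    basis of the blob-ELLR folding:

    * point reflection: ``project(-x, -y, theta) == -project(x, y, theta)``
    * tilt mirror:      ``project(-x, y, -theta) == -project(x, y, theta)``
    """
    t = np.radians(theta_deg)
    return x * np.cos(t) + y * np.sin(t)


@dataclass(frozen=True)
class TiltGeometry:
    """Tilt-angle list plus detector sampling for one single-axis tilt series.

    Attributes
    ----------
    angles_deg
        Strictly ascending tilt angles in degrees, all inside (-90, 90).
    n_rays
        Number of detector bins per view (``S``), unit spacing.
    """

    angles_deg: np.ndarray
    n_rays: int

    def __post_init__(self):
        angles = np.asarray(self.angles_deg, dtype=np.float64)
        if angles.ndim != 1 or angles.size == 0:
            raise ValueError("tilt angle list must be a nonempty 1-D sequence")
        if self.n_rays < 4:
            raise ValueError(f"n_rays must be >= 4, got {self.n_rays}")
        bad = angles[(angles <= -90.0) | (angles >= 90.0)]
        if bad.size:
            raise ValueError(f"tilt angle {bad[0]:g} deg outside the open range (-90, 90)")
        diffs = np.diff(angles)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(
                f"tilt angles must be strictly ascending; angle {angles[i + 1]:g} deg "
                f"at position {i + 1} does not increase on {angles[i]:g}"
            )
        object.__setattr__(self, "angles_deg", angles)

    @property
    def n_views(self) -> int:
        """Number of projection views ``B``."""
        return int(self.angles_deg.size)

    @property
    def n_values(self) -> int:
        """Total projection values per slice plane, ``M = B*S``."""
        return self.n_views * self.n_rays

    @property
    def detector_origin(self) -> float:
        """Array index of detector coordinate 0 (projection of the tilt axis)."""
        return (self.n_rays - 1) / 2.0

    @property
    def angles_rad(self) -> np.ndarray:
        return np.radians(self.angles_deg)

    def symmetric_about_zero(self, tol_deg: float = ANGLE_MATCH_TOL_DEG) -> bool:
        """True iff for every angle theta, -theta is also present (within tol).

        Since the list is ascending this is equivalent to
        ``angles[v] == -angles[B-1-v]`` for all ``v``, which is the pairing the
        tilt-mirror folding of the weight matrix relies on.
        """
        return bool(np.all(np.abs(self.angles_deg + self.angles_deg[::-1]) <= tol_deg))


def make_geometry(angles_deg, n_rays: int) -> TiltGeometry:
    """Validate a tilt-angle list and build a :class:`TiltGeometry`."""
    return TiltGeometry(np.asarray(angles_deg, dtype=np.float64), int(n_rays))


@dataclass(frozen=True)
class PixelGrid:
    """A centered ``n_x`` x ``n_z`` slice-plane pixel grid.

    Pixels are enumerated row-major as ``j = iz*n_x + ix`` so that the point
    reflection ``(x, z) -> (-x, -z)`` is exactly the index reversal
    ``j -> N-1-j`` and the in-plane mirror ``x -> -x`` is a per-row reversal.
    """

    n_x: int
    n_z: int
    centers_x: np.ndarray = field(init=False, repr=False)
    centers_z: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.n_x < 1 or self.n_z < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.n_x}x{self.n_z}")
        object.__setattr__(self, "centers_x", pixel_centers(self.n_x))
        object.__setattr__(self, "centers_z", pixel_centers(self.n_z))

    @property
    def n_pixels(self) -> int:
        """Unknown count per slice plane, ``N = n_x*n_z``."""
        return self.n_x * self.n_z

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (x, z) center coordinates for pixels ``j = 0..N-1``."""
        z, x = np.meshgrid(self.centers_z, self.centers_x, indexing="ij")
        return x.ravel(), z.ravel()

    @property
    def mirror_x_perm(self) -> np.ndarray:
        """Permutation sending pixel ``(x, z)`` to ``(-x, z)``."""
        idx = np.arange(self.n_pixels).reshape(self.n_z, self.n_x)
        return idx[:, ::-1].ravel()
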