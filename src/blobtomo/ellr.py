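"""blob-ELLR: symmetry-folded ELLPACK-style storage of the projection weights.

For one slice plane the projection model is ``p_i ≈ Σ_j w_ij x_j`` with
``M = B*S`` rays and ``N`` pixels.  With a radius-2 blob and unit ray spacing a
pixel projecting to detector position ``rf`` touches exactly the four rays
``floor(rf)-1 .. floor(rf)+2``; the ray-center distances of that window are all
determined by the single offset ``w1 = 1 - frac(rf) ∈ (0, 1]``:

    w0 = 1 + w1,   w2 = 1 - w1,   w3 = 2 - w1.

blob-ELLR therefore stores, per (view, pixel), only ``w1`` (float array ``A``)
and the base ray index (integer array ``I``) — no per-column length array is
needed because almost every column is full.  Three geometric symmetries fold
the storage further:

* Symmetry 1 — store ``w1`` instead of the four window distances (×1/4);
* Symmetry 2 — the point reflection ``(x,z) -> (-x,-z)`` flips the sign of the
  detector coordinate, so only half the pixels need storing (×1/2);
* Symmetry 3 — for a ±-paired tilt-angle set, ``(x,z)`` at angle ``-θ`` shares
  its magnitude with ``(-x,z)`` at ``θ``, so only half the views need storing
  (×1/2),

for ~1/16 of the unfolded ``(4B) × N`` arrays.  Weights are obtained at
application time as footprint values F(distance); distances, not weights, are
what the arrays hold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .blob import BlobParams, FootprintTable, linear_footprint, make_footprint_table
from .geometry import PixelGrid, TiltGeometry, project_point

#: Guard for the dense test oracle: refuse to materialize matrices above this.
DENSE_ORACLE_MAX_ENTRIES = 8_000_000

#: Storage accounting: single-precision float + 32-bit int per stored entry,
#: the layout the ~3.5 GB unfolded-matrix estimate assumes.
BYTES_PER_ENTRY = 8


@dataclass(frozen=True)
class WeightStats:
    """Entry count and byte accounting of a (possibly folded) weight matrix."""

    stored_entries: int
    nbytes: int
    ratio_vs_unsym: float


def split_ray_offset(rf: float) -> tuple[int, float]:
    """Split a detector position into (base ray, stored offset w1).

    ``base = floor(rf)`` (floor, not truncation, so the convention survives
    negative positions) and ``w1 = 1 - (rf - base) ∈ (0, 1]``; an integer hit
    gives ``(rf, 1.0)``.  The four contributing rays are ``base-1 .. base+2``.
    """
    base = math.floor(rf)
    return base, 1.0 - (rf - base)


def projected_offset(pixel_x: float, pixel_z: float, theta_deg: float,
                     geom: TiltGeometry) -> tuple[int, float]:
    """Project a pixel center and return its (base ray index, offset w1).

    The detector position is expressed in array-index units (tilt axis at
    ``geom.detector_origin``).  Rays outside ``[0, S)`` are not an error here;
    they are dropped when weights are applied.
    """
    rf = project_point(pixel_x, pixel_z, theta_deg) + geom.detector_origin
    return split_ray_offset(rf)


def neighbor_distances(w1: float) -> tuple[float, float, float]:
    """Distances of the other three window rays given the stored offset w1."""
    if not 0.0 < w1 <= 1.0:
        raise ValueError(f"stored offset w1 must lie in (0, 1], got {w1}")
    return 1.0 + w1, 1.0 - w1, 2.0 - w1


def _resolve_footprint(params: BlobParams, mode: str, table_step: float):
    if mode == "blob":
        return make_footprint_table(params, table_step)
    if mode == "linear":
        return linear_footprint
    raise ValueError(f"unknown footprint mode {mode!r} (expected 'blob' or 'linear')")


class BlobEllr:
    """Folded per-slice-plane weight matrix.

    Build with :func:`build`.  ``A`` and ``I`` are the stored offset / base-ray
    arrays; their shape depends on ``symmetry_level``:

    ========  =====================
    level     A, I shape
    ========  =====================
    0         (4B, N)  window distances + ray indices
    1         (B, N)   w1 + base ray
    2         (B, ceil(N/2))
    3         (ceil(B/2), ceil(N/2))
    ========  =====================

    Expansion reconstructs the detector position ``rf`` of any (view, pixel)
    from the stored arrays alone via the sign-flip symmetries, then evaluates
    weights as footprint values of the window distances.
    """

    def __init__(self, geom: TiltGeometry, grid: PixelGrid, params: BlobParams,
                 symmetry_level: int, A: np.ndarray, I: np.ndarray, footprint):
        self.geom = geom
        self.grid = grid
        self.params = params
        self.symmetry_level = int(symmetry_level)
        self.A = A
        self.I = I
        self.footprint = footprint
        self._col_sums = None
        self._row_sums = None
        self._window_cache: dict[int, tuple] = {}

    # -- basic sizes -------------------------------------------------------
    @property
    def n_views(self) -> int:
        return self.geom.n_views

    @property
    def n_pixels(self) -> int:
        return self.grid.n_pixels

    @property
    def shape(self) -> tuple[int, int]:
        """Logical (M, N) shape of the represented weight matrix."""
        return self.geom.n_values, self.grid.n_pixels

    # -- expansion ---------------------------------------------------------
    def _rf_index(self, view: int) -> np.ndarray:
        """Detector positions (array-index units) of all N pixels in one view."""
        B, N, S = self.n_views, self.n_pixels, self.geom.n_rays
        if not 0 <= view < B:
            raise IndexError(f"view index {view} out of range [0, {B})")
        lvl = self.symmetry_level
        if lvl == 0:
            # row 4v+2 stores the distance to ray base+1, which is w1
            return self.I[4 * view + 2].astype(np.float64) - self.A[4 * view + 2]
        Bh = (B + 1) // 2
        Nh = (N + 1) // 2
        if lvl == 3 and view >= Bh:
            # tilt mirror: rf(theta, pixel) = -rf(-theta, x-mirrored pixel)
            partner = self._rf_index(B - 1 - view)
            return (S - 1) - partner[self.grid.mirror_x_perm]
        rf_stored = (self.I[view] + 1).astype(np.float64) - self.A[view]
        if lvl == 1:
            return rf_stored
        # point reflection: pixel N-1-j is pixel j reflected through the center
        rf = np.empty(N, dtype=np.float64)
        rf[:Nh] = rf_stored
        rf[Nh:] = (S - 1) - rf_stored[N - 1 - Nh :: -1]
        return rf

    def _view_window(self, view: int):
        """Rays, weights and validity mask of the 4-ray windows of one view.

        Cached per view: SIRT applies the operator hundreds of times with the
        same geometry.  The cache is derived data only — expansion still goes
        through the stored A/I arrays.
        """
        cached = self._window_cache.get(view)
        if cached is not None:
            return cached
        S = self.geom.n_rays
        rf = self._rf_index(view)
        base = np.floor(rf).astype(np.int64)
        rays = base[None, :] + np.arange(-1, 3, dtype=np.int64)[:, None]  # (4, N)
        dist = np.abs(rf[None, :] - rays)
        w = self.footprint(dist)
        valid = (rays >= 0) & (rays < S)
        out = (rays, np.where(valid, w, 0.0), valid)
        self._window_cache[view] = out
        return out

    def expand_pixel_view(self, pixel_j: int, view_i: int):
        """The ≤4 (ray_index, weight) pairs of one pixel in one view.

        Off-detector rays are dropped; zero-weight in-window rays are kept so
        the window structure stays visible.
        """
        N = self.n_pixels
        if not 0 <= pixel_j < N:
            raise IndexError(f"pixel index {pixel_j} out of range [0, {N})")
        rays, w, valid = self._view_window(view_i)
        keep = valid[:, pixel_j]
        return list(zip(rays[keep, pixel_j].tolist(), w[keep, pixel_j].tolist()))

    def materialize(self) -> np.ndarray:
        """Expand to the dense M x N matrix (test scale only)."""
        M, N = self.shape
        if M * N > DENSE_ORACLE_MAX_ENTRIES:
            raise ValueError(f"refusing to materialize a {M}x{N} dense matrix")
        S = self.geom.n_rays
        W = np.zeros((M, N), dtype=np.float64)
        cols = np.arange(N)
        for v in range(self.n_views):
            rays, w, valid = self._view_window(v)
            block = W[v * S : (v + 1) * S]
            for k in range(4):
                m = valid[k]
                block[rays[k, m], cols[m]] += w[k, m]
        return W

    # -- application -------------------------------------------------------
    def apply_forward(self, x: np.ndarray) -> np.ndarray:
        """Reprojection ``p'_i = Σ_j w_ij x_j`` (length-M result)."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.n_pixels,):
            raise ValueError(f"expected coefficient vector of length {self.n_pixels}, "
                             f"got shape {x.shape}")
        S = self.geom.n_rays
        p = np.zeros(self.geom.n_values, dtype=np.float64)
        for v in range(self.n_views):
            rays, w, valid = self._view_window(v)
            block = p[v * S : (v + 1) * S]
            contrib = w * x[None, :]
            for k in range(4):
                m = valid[k]
                np.add.at(block, rays[k, m], contrib[k, m])
        return p

    def apply_transpose(self, r: np.ndarray) -> np.ndarray:
        """Backprojection ``y_j = Σ_i w_ij r_i`` (length-N result)."""
        r = np.asarray(r, dtype=np.float64)
        M = self.geom.n_values
        if r.shape != (M,):
            raise ValueError(f"expected projection vector of length {M}, got shape {r.shape}")
        S = self.geom.n_rays
        y = np.zeros(self.n_pixels, dtype=np.float64)
        for v in range(self.n_views):
            rays, w, valid = self._view_window(v)
            block = r[v * S : (v + 1) * S]
            for k in range(4):
                m = valid[k]
                y[m] += w[k, m] * block[rays[k, m]]
        return y

    def weight_sums(self) -> tuple[np.ndarray, np.ndarray]:
        """(per-pixel Σ_i w_ij, per-ray Σ_h w_ih) — the SIRT normalizers.

        Zeros mark pixels/rays untouched by any weight (legitimately present
        in limited-angle geometries); they are reported, not raised on.
        """
        if self._col_sums is None:
            self._col_sums = self.apply_transpose(np.ones(self.geom.n_values))
            self._row_sums = self.apply_forward(np.ones(self.n_pixels))
        return self._col_sums, self._row_sums

    # -- accounting --------------------------------------------------------
    def storage_stats(self) -> WeightStats:
        """Stored entries and bytes versus the unfolded (4B) x N baseline."""
        entries = int(self.A.size)
        baseline = 4 * self.n_views * self.n_pixels
        return WeightStats(entries, BYTES_PER_ENTRY * entries, entries / baseline)


def storage_forecast(n_views: int, n_pixels: int, symmetry_level: int) -> WeightStats:
    """Analytic blob-ELLR storage accounting, no arrays allocated.

    Lets the multi-GB unfolded estimate for production-size slice planes
    (e.g. 2048 x 430 pixels, 119 views) be checked instantly.
    """
    B, N = int(n_views), int(n_pixels)
    if symmetry_level == 0:
        entries = 4 * B * N
    elif symmetry_level == 1:
        entries = B * N
    elif symmetry_level == 2:
        entries = B * ((N + 1) // 2)
    elif symmetry_level == 3:
        entries = ((B + 1) // 2) * ((N + 1) // 2)
    else:
        raise ValueError(f"symmetry level must be 0..3, got {symmetry_level}")
    return WeightStats(entries, BYTES_PER_ENTRY * entries, entries / (4 * B * N))


def build(geom: TiltGeometry, grid: PixelGrid, params: BlobParams = BlobParams(),
          symmetry_level: int = 3, footprint_mode: str = "blob",
          table_step: float = 1e-3, on_downgrade: str = "warn") -> BlobEllr:
    """Build the blob-ELLR arrays for one slice-plane geometry.

    ``symmetry_level`` 3 needs a ±-paired tilt-angle set (a 0° view and odd
    grid dimensions are fine: self-paired centers are stored explicitly via the
    ceil shapes).  If the angle set is not paired the build degrades to level 2
    and either warns or raises per ``on_downgrade`` ('warn' | 'error').
    """
    if symmetry_level not in (0, 1, 2, 3):
        raise ValueError(f"symmetry level must be 0..3, got {symmetry_level}")
    if symmetry_level == 3 and not geom.symmetric_about_zero():
        msg = ("symmetry level 3 requires a tilt-angle set symmetric about zero; "
               "degrading to level 2")
        if on_downgrade == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        symmetry_level = 2

    footprint = _resolve_footprint(params, footprint_mode, table_step)
    B, N, S = geom.n_views, grid.n_pixels, geom.n_rays
    x, z = grid.coords()
    # (B, N) detector positions in array-index units
    rf = project_point(x[None, :], z[None, :],
                       geom.angles_deg[:, None]) + geom.detector_origin
    base = np.floor(rf).astype(np.int64)
    frac = rf - base
    w1 = 1.0 - frac

    if symmetry_level == 0:
        A = np.empty((4 * B, N), dtype=np.float64)
        I = np.empty((4 * B, N), dtype=np.int64)
        for k in range(4):
            A[k::4] = np.abs(rf - (base + k - 1))
            I[k::4] = base + k - 1
    else:
        Bh = (B + 1) // 2
        Nh = (N + 1) // 2
        rows = slice(0, Bh) if symmetry_level == 3 else slice(0, B)
        cols = slice(0, Nh) if symmetry_level >= 2 else slice(0, N)
        A = np.ascontiguousarray(w1[rows, cols])
        I = np.ascontiguousarray(base[rows, cols])
    return BlobEllr(geom, grid, params, symmetry_level, A, I, footprint)


def dense_oracle(geom: TiltGeometry, grid: PixelGrid, params: BlobParams = BlobParams(),
                 footprint=None, table_step: float = 1e-3) -> np.ndarray:
    """Brute-force dense M x N weight matrix for tests.

    Every entry is computed directly as ``F(|rf_ij - ray_i|)`` from the
    projection of pixel j in view i — no symmetry folding, no 4-ray window
    logic — so it is an independent reference for the blob-ELLR expansion.
    """
    M, N = geom.n_values, grid.n_pixels
    if M * N > DENSE_ORACLE_MAX_ENTRIES:
        raise ValueError(f"dense oracle capped at {DENSE_ORACLE_MAX_ENTRIES} entries, "
                         f"requested {M}x{N}")
    if footprint is None:
        footprint = make_footprint_table(params, table_step)
    S = geom.n_rays
    x, z = grid.coords()
    rays = np.arange(S, dtype=np.float64)
    W = np.empty((M, N), dtype=np.float64)
    for v, theta in enumerate(geom.angles_deg):
        rf = project_point(x, z, theta) + geom.detector_origin  # (N,)
        W[v * S : (v + 1) * S] = footprint(np.abs(rf[None, :] - rays[:, None]))
    return W


def save_blob_ellr(path, ellr: BlobEllr) -> None:
    """Serialize a built BlobEllr (arrays + geometry attributes) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=ellr.A)
        f.create_dataset("I", data=ellr.I)
        f.attrs["angles_deg"] = ellr.geom.angles_deg
        f.attrs["n_rays"] = ellr.geom.n_rays
        f.attrs["n_x"] = ellr.grid.n_x
        f.attrs["n_z"] = ellr.grid.n_z
        f.attrs["symmetry_level"] = ellr.symmetry_level
        f.attrs["blob_a"] = ellr.params.a
        f.attrs["blob_m"] = ellr.params.m
        f.attrs["blob_alpha"] = ellr.params.alpha
        f.attrs["footprint_mode"] = (
            "linear" if ellr.footprint is linear_footprint else "blob"
        )
        if isinstance(ellr.footprint, FootprintTable):
            f.attrs["table_step"] = ellr.footprint.step


def load_blob_ellr(path) -> BlobEllr:
    """Load a BlobEllr previously written by :func:`save_blob_ellr`."""
    import h5py

    with h5py.File(path, "r") as f:
        geom = TiltGeometry(np.asarray(f.attrs["angles_deg"]), int(f.attrs["n_rays"]))
        grid = PixelGrid(int(f.attrs["n_x"]), int(f.attrs["n_z"]))
        params = BlobParams(float(f.attrs["blob_a"]), int(f.attrs["blob_m"]),
                            float(f.attrs["blob_alpha"]))
        mode = str(f.attrs["footprint_mode"])
        step = float(f.attrs.get("table_step", 1e-3))
        footprint = _resolve_footprint(params, mode, step)
        return BlobEllr(geom, grid, params, int(f.attrs["symmetry_level"]),
                        f["A"][()], f["I"][()], footprint)
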