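"""Slab-parallel 3-D reconstruction with redundant (halo) slices.

The single-axis tilt geometry lets the volume be cut into contiguous *slabs* of
slice planes orthogonal to the tilt axis, one per worker.  Because blobs
overlap neighbouring slices the slabs are interdependent: each slab carries
redundant *halo* slices borrowed from its neighbours (one slice per boundary
for blob radius 2), and per iteration there are exactly two boundary exchanges:

1. after the reprojection stage — computed projections of the halo slices;
2. after the backprojection stage — pixel-space corrections of the halo slices.

Cross-slice coupling uses a separable axial-footprint approximation: the blob
footprint evaluated at integer slice offsets, normalized to a unit sum,

    g(Δ) = F(|Δ|) / (F(0) + 2 F(1)),   Δ ∈ {-1, 0, +1},

so the per-plane weight matrix W is shared by all slices and the 3-D forward
model is the separable operator  (Ω x)[y] = Σ_Δ g(Δ) · W x[y+Δ].  Each plane y
is reconstructed by SIRT against its *effective sinogram*
``p_eff[y] = Σ_Δ g(Δ) p[y+Δ]``, with computed projections gathered the same
way and backprojected corrections redistributed with the same g.  At the
volume edges g is renormalized over the in-range offsets, so a single-slice
volume reduces exactly to the 2-D SIRT.

The multi-worker scheme is executed in-process with deterministic stage order
and owner-authoritative halo copies, so 1-, 2- and 4-worker runs — and the
synchronous versus boundary-first asynchronous schedules — produce identical
volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blob import BlobParams, make_footprint_table
from .ellr import build as build_ellr
from .geometry import PixelGrid, TiltGeometry
from .sirt import SirtConfig


def halo_width(blob_a: float) -> int:
    """Redundant slices needed per slab boundary: ``ceil(a) - 1`` (1 for a=2)."""
    return max(0, math.ceil(blob_a) - 1)


@dataclass(frozen=True)
class Slab:
    """One worker's contiguous slice range plus its halo slice indices."""

    start: int
    stop: int
    halo_lo: int | None = None
    halo_hi: int | None = None

    @property
    def own(self) -> range:
        return range(self.start, self.stop)

    @property
    def halos(self) -> tuple[int, ...]:
        return tuple(h for h in (self.halo_lo, self.halo_hi) if h is not None)


def decompose_slabs(n_slices: int, n_workers: int, blob_a: float = 2.0) -> list[Slab]:
    """Split ``[0, n_slices)`` into balanced contiguous slabs with halos.

    Own ranges partition the slice index set exactly and differ in size by at
    most 1 (the remainder goes to the leading slabs).  Interior slabs get a
    halo on both sides, edge slabs on their single interior boundary; with a
    halo width of 0 (blob radius <= 1) no halos exist at all.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    if n_workers > n_slices:
        raise ValueError(f"n_workers ({n_workers}) exceeds n_slices ({n_slices})")
    h = halo_width(blob_a)
    if h > 1:
        raise ValueError(f"blob radius {blob_a} couples beyond adjacent slices; "
                         "only a <= 2 is supported")
    base, extra = divmod(n_slices, n_workers)
    slabs, start = [], 0
    for w in range(n_workers):
        stop = start + base + (1 if w < extra else 0)
        halo_lo = start - 1 if (h and w > 0) else None
        halo_hi = stop if (h and w < n_workers - 1) else None
        slabs.append(Slab(start, stop, halo_lo, halo_hi))
        start = stop
    return slabs


def axial_weights(params: BlobParams = BlobParams(), footprint=None) -> dict[int, float]:
    """Normalized cross-slice coupling weights ``g(Δ)`` for Δ in {-1, 0, +1}."""
    if params.a > 2.0:
        raise ValueError(f"axial coupling is only supported for blob radius <= 2 "
                         f"(adjacent slices), got a={params.a}")
    if footprint is None:
        footprint = make_footprint_table(params)
    g0 = float(footprint(0.0))
    g1 = float(footprint(1.0))
    norm = g0 + 2.0 * g1
    return {-1: g1 / norm, 0: g0 / norm, 1: g1 / norm}


@dataclass(frozen=True)
class ExchangeSpec:
    """What one boundary exchange ships, and when."""

    phase: str
    payload: str
    per_slice_shape: tuple
    exchanges_per_iteration: int
    schedule: str


def exchange_contract(phase: str, geom: TiltGeometry | None = None,
                      grid: PixelGrid | None = None) -> ExchangeSpec:
    """Describe the boundary-exchange payload of one pipeline phase.

    With a zero-width halo (blob radius <= 1) no exchange occurs at all; the
    shapes below are per redundant slice.
    """
    B = geom.n_views if geom is not None else None
    S = geom.n_rays if geom is not None else None
    N = grid.n_pixels if grid is not None else None
    if phase == "reprojection":
        return ExchangeSpec(
            phase=phase,
            payload="computed projections (B x S floats) of each halo slice",
            per_slice_shape=(B, S),
            exchanges_per_iteration=1,
            schedule="after the reprojection stage; async mode reprojects "
                     "boundary slices first and overlaps their shipment with "
                     "interior-slice reprojection",
        )
    if phase == "backprojection":
        return ExchangeSpec(
            phase=phase,
            payload="backprojected pixel corrections (N floats) of each halo slice",
            per_slice_shape=(N,),
            exchanges_per_iteration=1,
            schedule="after the backprojection stage; async mode backprojects "
                     "boundary slices first and overlaps their shipment with "
                     "interior-slice backprojection",
        )
    raise ValueError(f"unknown phase {phase!r} (expected 'reprojection' or 'backprojection')")


@dataclass
class VolumeJob:
    """A full 3-D reconstruction task.

    ``tilt_series`` has shape (B, n_slices, S): per view, one row of detector
    values for every slice along the tilt axis.
    """

    tilt_series: np.ndarray
    geom: TiltGeometry
    grid: PixelGrid
    blob: BlobParams = BlobParams()
    sirt: SirtConfig = SirtConfig()
    n_workers: int = 1
    exchange_mode: str = "sync"
    symmetry_level: int = 3

    def __post_init__(self):
        self.tilt_series = np.asarray(self.tilt_series, dtype=np.float64)
        B, S = self.geom.n_views, self.geom.n_rays
        if self.tilt_series.ndim != 3 or self.tilt_series.shape[0] != B \
                or self.tilt_series.shape[2] != S:
            raise ValueError(f"tilt series shape {self.tilt_series.shape} does not match "
                             f"geometry (B={B}, n_slices, S={S})")
        if self.exchange_mode not in ("sync", "async"):
            raise ValueError(f"unknown exchange mode {self.exchange_mode!r}")
        if not (1 <= self.n_workers <= self.n_slices):
            raise ValueError(f"n_workers must be in [1, {self.n_slices}], "
                             f"got {self.n_workers}")

    @property
    def n_slices(self) -> int:
        return int(self.tilt_series.shape[1])


@dataclass
class ExchangeRecord:
    iteration: int
    phase: str
    src: int
    dst: int
    slice_index: int
    payload: np.ndarray
    owner_value: np.ndarray


@dataclass
class ReconResult:
    """Reconstructed volume plus scheduling/diagnostic bookkeeping."""

    volume: np.ndarray
    residual_history: list
    slabs: list
    exchange_events: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    stage_order: dict = field(default_factory=dict)


class _Worker:
    """One slab's state within the in-process message-passing scheme."""

    def __init__(self, wid: int, slab: Slab, job: VolumeJob, ellr, g: dict[int, float]):
        self.wid = wid
        self.slab = slab
        self.job = job
        self.ellr = ellr
        self.g = g
        n = job.n_slices
        # renormalized axial weights per own slice (edge slices lose offsets)
        self.g_tilde = {}
        for y in slab.own:
            valid = [(d, g[d]) for d in sorted(g) if 0 <= y + d < n]
            norm = sum(w for _, w in valid)
            self.g_tilde[y] = [(d, w / norm) for d, w in valid]
        # effective (axially gathered) measured sinograms for own slices
        self.p_eff = {
            y: sum(w * job.tilt_series[:, y + d, :].ravel()
                   for d, w in self.g_tilde[y])
            for y in slab.own
        }
        self.x: dict[int, np.ndarray] = {}
        self.q: dict[int, np.ndarray] = {}
        self.back: dict[int, np.ndarray] = {}
        self.halo_q: dict[int, np.ndarray] = {}
        self.halo_back: dict[int, np.ndarray] = {}
        col, row = ellr.weight_sums()
        self.col, self.row = col, row

    def stage_order(self) -> list[int]:
        """Own-slice processing order: boundary slices first in async mode."""
        own = list(self.slab.own)
        if self.job.exchange_mode != "async":
            return own
        boundary = [y for y in (own[0], own[-1]) if
                    (y == own[0] and self.slab.halo_lo is not None) or
                    (y == own[-1] and self.slab.halo_hi is not None)]
        boundary = list(dict.fromkeys(boundary))
        return boundary + [y for y in own if y not in boundary]

    def bpt(self):
        for y in self.slab.own:
            yv = self.ellr.apply_transpose(self.p_eff[y])
            self.x[y] = np.divide(yv, self.col, out=np.zeros_like(yv),
                                  where=self.col > 0)

    def reproject(self, order):
        for y in order:
            self.q[y] = self.ellr.apply_forward(self.x[y])

    def _q_at(self, y):
        if y in self.q:
            return self.q[y]
        return self.halo_q[y]

    def backproject(self, order):
        """Residuals against the axially gathered computed projections."""
        sq_res = 0.0
        for y in order:
            q_eff = sum(w * self._q_at(y + d) for d, w in self.g_tilde[y])
            r = self.p_eff[y] - q_eff
            sq_res += float(r @ r)
            rn = np.divide(r, self.row, out=np.zeros_like(r), where=self.row > 0)
            self.back[y] = self.ellr.apply_transpose(rn)
        return sq_res

    def _back_at(self, y):
        if y in self.back:
            return self.back[y]
        return self.halo_back[y]

    def update(self):
        lam = self.job.sirt.relaxation
        for y in self.slab.own:
            dx = sum(w * self._back_at(y + d) for d, w in self.g_tilde[y])
            dx = np.divide(dx, self.col, out=np.zeros_like(dx), where=self.col > 0)
            self.x[y] = self.x[y] + lam * dx
            if not np.all(np.isfinite(self.x[y])):
                raise FloatingPointError(f"non-finite values in slice {y}")


def reconstruct_volume(job: VolumeJob, collect_trace: bool = False) -> ReconResult:
    """Run the slab-parallel blob-SIRT reconstruction of a whole volume.

    The workers advance in lockstep through the stages of each iteration
    (reprojection -> exchange -> backprojection -> exchange -> update); halo
    payloads are owner-authoritative copies, so the result is independent of
    the worker count and of the sync/async schedule.
    """
    ellr = build_ellr(job.geom, job.grid, job.blob, job.symmetry_level,
                      footprint_mode=job.sirt.footprint_mode)
    h = halo_width(job.blob.a)
    g = axial_weights(job.blob, ellr.footprint) if h > 0 else {0: 1.0}
    slabs = decompose_slabs(job.n_slices, job.n_workers, job.blob.a)
    workers = [_Worker(i, s, job, ellr, g) for i, s in enumerate(slabs)]
    owner_of = {y: w for w in workers for y in w.slab.own}

    trace: list[ExchangeRecord] = []
    events: dict[str, int] = {"reprojection": 0, "backprojection": 0}

    def exchange(phase: str, iteration: int):
        """Ship boundary-slice data into neighbour halos (one event/boundary)."""
        for w in workers:
            for y in w.slab.halos:
                owner = owner_of[y]
                src = owner.q if phase == "reprojection" else owner.back
                payload = src[y].copy()
                dst = w.halo_q if phase == "reprojection" else w.halo_back
                dst[y] = payload
                events[phase] += 1
                if collect_trace:
                    trace.append(ExchangeRecord(iteration, phase, owner.wid,
                                                w.wid, y, payload, src[y].copy()))

    for w in workers:
        w.bpt()

    residuals = []
    orders = {w.wid: w.stage_order() for w in workers}
    for it in range(job.sirt.n_iters):
        for w in workers:
            w.reproject(orders[w.wid])
        exchange("reprojection", it)
        sq = 0.0
        for w in workers:
            sq += w.backproject(orders[w.wid])
        exchange("backprojection", it)
        residuals.append(math.sqrt(sq))
        for w in workers:
            w.update()

    volume = np.empty((job.n_slices, job.grid.n_z, job.grid.n_x), dtype=np.float64)
    for w in workers:
        for y in w.slab.own:
            volume[y] = w.x[y].reshape(job.grid.n_z, job.grid.n_x)
    return ReconResult(volume=volume, residual_history=residuals, slabs=slabs,
                       exchange_events=dict(events), trace=trace,
                       stage_order=orders)
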