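"""SIRT iterations with back-projection (BPT) initialization for one slice plane.

The simultaneous iterative reconstruction technique solves ``p ≈ W x`` by
refining all coefficients at once from all views per iteration:

    x_j^(0)   = Σ_i w_ij p_i / Σ_i w_ij                       (BPT init)
    x_j^(k+1) = x_j^(k) + λ/Σ_i w_ij · Σ_i w_ij (p_i - Σ_h w_ih x_h^(k)) / Σ_h w_ih

i.e. residuals are normalized per ray (Σ_h w_ih) and the backprojected
correction per pixel (Σ_i w_ij).  λ is a relaxation factor; the default λ = 1
is the classic update.  Rays or pixels with zero weight sum (legitimate in
limited-angle geometries) simply contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ellr import BlobEllr


@dataclass(frozen=True)
class SirtConfig:
    """Iteration settings.

    n_iters
        Fixed iteration count (no residual-based early stopping, for
        reproducibility); typical reconstruction practice uses 1-25.
    relaxation
        Step scaling λ in (0, 2]; 1.0 reproduces the unrelaxed update.
    footprint_mode
        'blob' (Kaiser-Bessel footprint weights, the primary semantics) or
        'linear' (triangular voxel-style weights for comparison runs).
    """

    n_iters: int = 25
    relaxation: float = 1.0
    footprint_mode: str = "blob"

    def __post_init__(self):
        if self.n_iters < 0:
            raise ValueError(f"n_iters must be >= 0, got {self.n_iters}")
        if not 0.0 < self.relaxation <= 2.0:
            raise ValueError(f"relaxation must lie in (0, 2], got {self.relaxation}")
        if self.footprint_mode not in ("blob", "linear"):
            raise ValueError(f"unknown footprint mode {self.footprint_mode!r}")


@dataclass
class SirtState:
    """Current coefficient image plus iteration bookkeeping.

    ``residual_history[k]`` is ``||p - W x^(k)||_2`` evaluated at the start of
    step k+1 (the residual the update itself uses), so the history length
    always equals the iteration counter.
    """

    x: np.ndarray
    k: int = 0
    residual_history: list = field(default_factory=list)


def bpt_init(ellr: BlobEllr, p: np.ndarray) -> SirtState:
    """Weighted-backprojection starting estimate ``x_j = Σ w_ij p_i / Σ w_ij``.

    A constant sinogram maps to the same constant image; pixels never touched
    by any ray start at 0.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    M = ellr.geom.n_values
    if p.shape != (M,):
        raise ValueError(f"expected sinogram of length {M}, got shape {p.shape}")
    col_sums, _ = ellr.weight_sums()
    y = ellr.apply_transpose(p)
    x = np.divide(y, col_sums, out=np.zeros_like(y), where=col_sums > 0)
    return SirtState(x=x, k=0, residual_history=[])


def sirt_step(state: SirtState, ellr: BlobEllr, p: np.ndarray,
              cfg: SirtConfig = SirtConfig()) -> SirtState:
    """One SIRT update; returns a new state with k+1 and the residual appended."""
    p = np.asarray(p, dtype=np.float64).ravel()
    col_sums, row_sums = ellr.weight_sums()
    q = ellr.apply_forward(state.x)
    r = p - q
    residual = float(np.linalg.norm(r))
    rn = np.divide(r, row_sums, out=np.zeros_like(r), where=row_sums > 0)
    dx = ellr.apply_transpose(rn)
    dx = np.divide(dx, col_sums, out=np.zeros_like(dx), where=col_sums > 0)
    x = state.x + cfg.relaxation * dx
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite coefficients after iteration {state.k + 1}")
    return SirtState(x=x, k=state.k + 1,
                     residual_history=state.residual_history + [residual])


def run_sirt(ellr: BlobEllr, p: np.ndarray, cfg: SirtConfig = SirtConfig()) -> SirtState:
    """BPT initialization followed by ``cfg.n_iters`` SIRT steps."""
    state = bpt_init(ellr, p)
    for _ in range(cfg.n_iters):
        state = sirt_step(state, ellr, p, cfg)
    return state
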