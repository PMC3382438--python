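# blobtomo

Blob-based iterative 3-D reconstruction for single-axis-tilt electron
tomography (ET), built around three ideas:

* **Kaiser–Bessel blob basis functions.** The volume is expanded as
  `f ≈ Σ_j x_j b_j` over spherically symmetric, compactly supported blobs
  `b(r) = (√(1-(r/a)²))^m · I_m(α√(1-(r/a)²)) / I_m(α)` (defaults a=2, m=2,
  α=3.6).  Blobs are smoother than voxels and markedly more robust under the
  noisy, limited-angle (±60°) conditions of ET.
* **A symmetry-folded sparse weight matrix (blob-ELLR).** The projection
  model is `p_i ≈ Σ_j w_ij x_j` with `M = B·S` rays over `N` pixels per slice
  plane.  A radius-2 blob makes each pixel touch exactly four rays per view,
  whose distances are all determined by one stored offset
  `w1 = 1 - frac(rf) ∈ (0,1]` (`w0 = 1+w1`, `w2 = 1-w1`, `w3 = 2-w1`), and two
  exact sign symmetries of `project(x, y, θ) = x·cosθ + y·sinθ` — point
  reflection `(x,y) → (-x,-y)` and tilt mirror `(-x, y, -θ)` — fold storage to
  1/16 of the unfolded `(4B) × N` arrays.  Weights are recovered at
  application time as blob *footprint* values F(distance), the line integral
  of the blob.
* **SIRT with slab parallelism.** Reconstruction uses the simultaneous
  iterative reconstruction technique with weighted-backprojection (BPT)
  initialization,

      x_j⁽⁰⁾  = Σ_i w_ij p_i / Σ_i w_ij
      x_j⁽ᵏ⁺¹⁾ = x_j⁽ᵏ⁾ + λ/Σ_i w_ij · Σ_i w_ij (p_i − Σ_h w_ih x_h⁽ᵏ⁾) / Σ_h w_ih

  The volume is cut into slabs of slices along the tilt axis, one per worker;
  blob overlap couples adjacent slices, so each slab carries one redundant
  (halo) slice per boundary and per iteration performs exactly two boundary
  exchanges: computed projections after reprojection, pixel corrections after
  backprojection.  A boundary-first "async" schedule mirrors latency-hiding
  execution without changing any value.

Everything is exercised on synthetic phantoms (vesicle-like shells and
spheres) projected by an independent ray-driven simulator, so no external
data is needed and recovery tests are free of the inverse crime.  Intended
users: people building or studying ET reconstruction pipelines who want a
small, fully tested reference implementation of blob-SIRT and its storage
folding.

## Worked example

The package is a library; `examples/` holds one short script per capability.
Storage folding (`python examples/02_storage_folding.py`):

```
slice plane: 32x32 pixels, 8 views, 48 rays -> W is 384x1024
level   stored    ratio  max |folded - dense|
    0    32768   1.0000  0.00e+00
    1     8192   0.2500  0.00e+00
    2     4096   0.1250  6.00e-15
    3     2048   0.0625  6.00e-15
unfolded arrays for a 2048x430 plane, 119 views: 3.35 GB (4+4 bytes/entry)
```

Each folding level stores fewer entries (ratio vs the unfolded `(4B) × N`
arrays: 25%, 12.5%, 6.25%) while expanding to the *same* matrix as the dense
brute-force oracle — the last column is the largest entrywise deviation.  The
final lines show why folding matters: the unfolded weights of one
production-size slice plane already cost several GB.

End-to-end reconstruction (`python examples/04_volume_parallel.py`):

```
phantom (8, 64, 64), tilt series (31, 8, 64)
  BPT init: corr(truth) = 0.4354, rmse = 1.0642
  iter  1: corr(truth) = 0.5688, rmse = 0.4062
  iter 25: corr(truth) = 0.7251, rmse = 0.0775
  2 worker(s),  sync: max diff vs serial = 0.0e+00, exchanges = {'reprojection': 10, 'backprojection': 10}
```

Correlation with the ground-truth phantom rises monotonically from the BPT
start through SIRT iterations (perfect recovery is impossible from a ±60°
tilt range — the missing wedge), and slab-parallel runs reproduce the serial
result exactly while performing the two expected exchanges per iteration and
boundary.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

builds the folded weight matrix for a reference slice-plane geometry at
successive symmetry levels, counts the stored entries of each freshly built
instance, and writes the retained-storage percentage of the offset folding
and the additional reduction from the pixel point-reflection folding as JSON.
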