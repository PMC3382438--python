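# Methods

## Model

A specimen slice plane perpendicular to the tilt axis is expanded over
generalized Kaiser–Bessel (KB) blobs on the pixel grid.  The blob profile

    b(r) = (√(1-(r/a)²))^m · I_m(α·√(1-(r/a)²)) / I_m(α),   0 ≤ r ≤ a

is radially symmetric, so only the radial coordinate ever enters a
computation.  Projection is parallel-beam single-axis: a point (x, z) maps to
detector coordinate `r = x·cosθ + z·sinθ`.  The discrete model per slice
plane is `p ≈ W x` with `M = B·S` rays and `N = n_x·n_z` unknowns; `w_ij` is
the blob footprint `F(d_ij)`, the X-ray transform of the blob evaluated at
the perpendicular distance between ray i and the center of blob j.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `a` | 2 grid units | blob radius; with unit ray spacing gives the 4-ray window and 1-slice axial coupling |
| `m` | 2 | KB order; continuous derivative at the support edge |
| `α` | 3.6 | shape parameter; the standard smooth-reconstruction choice for this radius/order |
| `n_iters` | 25 | fixed SIRT iteration count (1/5/10/25 are the conventional checkpoints) |
| `λ` | 1.0 | relaxation; 1.0 is the unrelaxed classical update |
| table step | 1e-3 | footprint sampling interval; interpolation error ≤ 1e-6 |
| symmetry level | 3 | blob-ELLR folding (0 = unfolded … 3 = fully folded) |

## Coordinate conventions

Pixel centers are volume-centered at `j - (n-1)/2`; for even n they are
half-integers, so the point reflection `(x,z) → (-x,-z)` is a perfect pairing
with no fixed pixel and the "nearly 50%" folding steps become exactly 50%.
Detector bins sit at integers with the tilt axis projecting to array index
`(S-1)/2`.  Angles are degrees externally, radians internally; ±-pairing of
the angle list is detected with a 1e-6° tolerance because `.tlt` files carry
limited precision.

## blob-ELLR folding

The stored quantity per (view, pixel) is the *distance offset*
`w1 = 1 - frac(rf)` together with the base ray `floor(rf)` — not a final
weight.  The paper-level relations `w0 = 1+w1`, `w2 = 1-w1`, `w3 = 2-w1` only
make sense for distances (they exceed 1), so weights are produced at
application time as `F(distance)`; a triangular "linear" footprint
`max(0, 1-|d|)` is available to mimic voxel-style weighting in comparison
runs.  `floor` (not truncation) keeps the offset well-defined for negative
detector coordinates, which is what makes the point-reflection folding work
across zero.

Folding levels store: (0) all four window distances, `(4B) × N`; (1) one
offset per view, `B × N`; (2) only pixels `j < ⌈N/2⌉`, with the partner
`N-1-j` served by the sign flip `rf → (S-1) - rf`; (3) only views
`v < ⌈B/2⌉`, with the partner view served by the tilt-mirror flip combined
with an in-plane x-mirror permutation.  A 0° view and odd grid dimensions
pair with themselves and are stored explicitly via the ceil shapes — that
self-pairing is exactly why the headline ratio is "nearly", not exactly,
1/16 for odd counts.  No per-column length array is stored; off-detector rays
are dropped symmetrically from forward, transpose and both normalizers, which
keeps the operator pair an exact adjoint.

Numerical note: reconstructing `rf` from the stored `(base, w1)` round-trips
`1 - frac` through IEEE rounding and can move a distance by ~1 ulp relative
to the directly computed value.  Folded expansion therefore agrees with the
dense brute-force matrix to ≤ 1e-10 absolute (measured ~6e-15), not bit-for-
bit; all operator-level tests use 1e-10 relative tolerances.

Storage accounting assumes 4-byte floats and 4-byte ints per entry (the
GPU-style layout that makes a 2048×430 plane with 119 views cost ~3.35 GB
unfolded); in-memory arrays are float64/int64 for numerical fidelity.

## SIRT

BPT initialization and the update are implemented exactly as the normalized
form above, with per-ray normalization `Σ_h w_ih` inside the sum and per-pixel
normalization `Σ_i w_ij` outside.  Zero-sum rays and pixels (legitimate in
limited-angle geometries) contribute nothing instead of raising.  The stopping
rule is a fixed iteration count — no residual-based early stopping — for
reproducibility.  `residual_history[k]` records `‖p - W x⁽ᵏ⁾‖₂` as evaluated
by the update itself, so the history length equals the iteration counter and
a consistent fixed point records an exact 0.

## 3-D coupling and slab parallelism

Blob overlap couples adjacent slices.  The paper-level scheme leaves the
coupling form open; this implementation uses a separable axial-footprint
approximation: integer slice offsets Δ ∈ {-1, 0, +1} are weighted by
`g(Δ) = F(|Δ|)/(F(0) + 2F(1))` (≈ 0.556, 0.222, 0.222 at the defaults), so
the per-plane W is shared by every slice and the 3-D operator is
`(Ω x)[y] = Σ_Δ g(Δ)·W x[y+Δ]`.  Each plane is reconstructed by SIRT against
its effective sinogram `p_eff[y] = Σ_Δ g(Δ) p[y+Δ]`, with computed
projections gathered the same way and backprojected corrections redistributed
with the same g.  At volume edges g is renormalized over in-range offsets; a
single-slice volume therefore reduces *exactly* to the 2-D algorithm.

Slabs are contiguous, balanced (sizes differ by ≤ 1) and carry
`⌈a⌉ - 1 = 1` halo slice per interior boundary.  Per iteration each boundary
exchanges (1) halo-slice reprojections after the reprojection stage and
(2) halo-slice pixel corrections after the backprojection stage — two
exchanges, as the communication analysis of the multi-GPU scheme requires.
Halo payloads are owner-authoritative copies (replace, never sum).  The
"async" mode reorders each worker's stage loop boundary-first, modelling
communication/computation overlap; since per-slice arithmetic is unchanged
and accumulation order within a stage is fixed, sync and async results — and
1/2/4-worker results — are bitwise identical, which the tests assert.

## Synthetic data

The phantom generator voxelizes solid spheres and hollow shells
(vesicle/caveola-like objects) on the centered grid.  Containment is enforced
in-plane only: volumes are thin sections, and objects may be clipped by the
slab faces along the tilt axis exactly as real specimens are.  The reference
world is an 8×64×64 volume with two shells and two spheres, 31 views over
±60° in 4° steps, noiseless — limited-angle but clean, so recovery failures
indicate algorithmic faults rather than noise.  The simulator is a ray-driven
bilinear-interpolation projector (0.5-pixel sampling steps), deliberately
*not* the blob operator, to avoid the inverse crime; optional additive
Gaussian noise is seeded.  Green recovery tests therefore establish that
blob-SIRT improves truth correlation monotonically across checkpoints on
clean limited-angle data; they do not establish noise robustness, CTF/MTF
behaviour, or alignment tolerance, none of which are modelled.

## Numerical choices

* Footprint by quadrature: the scalar reference uses adaptive quadrature
  (relative tolerance 1e-10); the lookup table is built by fixed 96-point
  Gauss–Legendre rules, which are spectrally accurate here because the KB
  integrand is analytic in t² along the chord.  Table lookups interpolate
  linearly at step 1e-3 (max error ≤ 1e-6 vs quadrature, verified by
  sampling).
* Per-view expansion windows are cached on the operator object; the cache is
  derived data and every expansion still originates from the stored A/I
  arrays.
* α = 0 degenerates to the plain window `(1-(r/a)²)^(m/2)` and is handled
  explicitly (the Bessel normalization would be 0/0).
* Degenerate inputs: empty angle lists, non-ascending or out-of-range
  angles, undersized detectors, mismatched vector lengths and non-finite
  iterates all raise with the offending value named.

## Limitations

* Dual-axis geometry, projection alignment, CTF and dose weighting are out of
  scope.
* Blob radii above 2 grid units (coupling beyond adjacent slices) are
  rejected rather than approximated.
* The parallel scheme models message-passing structure in-process; it
  demonstrates algorithmic equivalence, not wall-clock scaling.
* MRC support covers the MRC2014 subset used in practice for ET maps (modes
  0/1/2/6 in, mode 2 out); extended headers are ignored.
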