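"""Slab-parallel 3-D reconstruction with redundant-slice exchange.

Simulates a noiseless tilt series of the reference vesicle phantom with the
independent ray-driven projector, reconstructs it with 1, 2 and 4 workers
under both exchange schedules, and shows that the slab decomposition does not
change the result while truth correlation improves over iterations.
"""

import numpy as np

import blobtomo as bt

geom = bt.make_geometry(np.arange(-60.0, 60.0 + 1e-9, 4.0), 64)
grid = bt.PixelGrid(64, 64)
spec = bt.PhantomSpec()  # 8x64x64, two shells + two spheres
truth = bt.make_phantom(spec)
series = bt.simulate_tilt_series(truth, geom, spec.noise_sigma, spec.seed)
print(f"phantom {truth.shape}, tilt series {series.shape}")

for n_iters in (0, 1, 25):
    job = bt.VolumeJob(series, geom, grid, sirt=bt.SirtConfig(n_iters=n_iters))
    recon = bt.reconstruct_volume(job).volume
    m = bt.recon_metrics(recon, truth)
    label = "BPT init" if n_iters == 0 else f"iter {n_iters:>2}"
    print(f"  {label}: corr(truth) = {m['pearson_r']:.4f}, rmse = {m['rmse']:.4f}")

ref = None
for workers in (1, 2, 4):
    for mode in ("sync", "async"):
        job = bt.VolumeJob(series, geom, grid, sirt=bt.SirtConfig(n_iters=5),
                           n_workers=workers, exchange_mode=mode)
        res = bt.reconstruct_volume(job)
        if ref is None:
            ref = res.volume
        diff = np.abs(res.volume - ref).max()
        print(f"  {workers} worker(s), {mode:>5}: max diff vs serial = {diff:.1e}, "
              f"exchanges = {res.exchange_events}")
print("slab decomposition and exchange schedule change the schedule, not the values;")
print("each boundary ships projections once and pixel corrections once per iteration.")
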