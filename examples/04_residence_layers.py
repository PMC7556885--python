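"""Layer-resolved residence times near a model biomolecular surface.

Generates walkers in a water slab whose surface layer is ten times
slower than the bulk-like top layer, extracts first-passage residence
times (3.5 A threshold), and prints per-layer means: mobility recovers
toward bulk with distance from the surface.
"""

import numpy as np

from hydrosub import (
    WaitingTimeModel,
    gen_layered_trajectories,
    layer_residence_distributions,
    residence_distribution,
    residence_times,
    second_moment,
)

models = [
    WaitingTimeModel(kind="exponential", mean=10.0),  # surface layer
    WaitingTimeModel(kind="exponential", mean=3.0),   # second layer
    WaitingTimeModel(kind="exponential", mean=1.0),   # bulk-like
]
obs = np.arange(0.0, 1000.25, 0.25)
traj = gen_layered_trajectories(
    models, n_particles=300, t_max=1000.0, seed=5,
    observation_times=obs, z_max=10.5,
)

rts = residence_times(traj, threshold=3.5)
mean, sq_dev = second_moment(rts)
dist = residence_distribution(rts)
print(f"pooled: {rts.n} samples, mean tau_res = {mean:.2f} ps, "
      f"<(tau - <tau>)^2> = {sq_dev:.1f} ps^2, "
      f"censored fraction {rts.censored_fraction:.3f}")

print("\nper-layer mean residence time (ps):")
for layer, d in layer_residence_distributions(traj).items():
    print(f"  layer {layer}: {d.mean():6.2f}   ({d.count} intervals)")
print("\nLayer 1 (surface) dwells longest; beyond layer 2 values approach the")
print("bulk waiting-time mean — the hydration shell is about two layers deep.")
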