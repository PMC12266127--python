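"""Select dynamic bins and cluster their temporal archetypes.

Bins whose methylation range across the course is >= 10 percentage points
are 'dynamic'; k-means on their delta-from-baseline trajectories recovers
the four planted archetypes (monotone gain, transient gain, transient
loss, monotone late loss), labelled by template correlation.
"""

from methdyn import (
    adjusted_rand_index,
    cluster_trajectories,
    simulate_bin_trajectories,
)
from methdyn.dynamics import select_dynamic_bins

traj, true_labels = simulate_bin_trajectories(1000, noise_sd=0.05, seed=7)
tps = {f"s{t}": float(t) for t in (0, 24, 96, 168)}
profiles = traj.rename(columns={f"t{t}": f"s{t}" for t in (0, 24, 96, 168)})

dynamic = select_dynamic_bins(profiles, tps, min_delta=0.10)
print(f"dynamic bins (range >= 10 pp): {len(dynamic)} of {len(traj)}")
print(dynamic["direction"].value_counts().to_string())

assignments = cluster_trajectories(dynamic, k=4, seed=7)
print("\ncluster sizes:")
print(assignments["cluster_label"].value_counts().to_string())

# compare against truth on the dynamic set (bins are 1 kb, keyed by start)
truth_dyn = true_labels[(dynamic["start"] // 1000).to_numpy()]
ari = adjusted_rand_index(assignments["cluster_label"], truth_dyn)
print(f"\nadjusted Rand index vs planted archetypes: {ari:.3f}")
# ARI near 1 means the four temporal archetypes were recovered almost
# perfectly at this noise level.
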