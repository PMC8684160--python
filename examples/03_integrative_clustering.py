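"""Recover subgroups by penalized latent-factor consensus clustering.

A desk-scale cohort (3 planted subgroups) is clustered with the
resampled consensus procedure: each iteration subsamples samples and
features, fits the latent model across K, and votes for the
BIC-optimal K; final labels cut the consensus matrix.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from omicsub.integrate import consensus_select_k
from omicsub.simulate import SimulationConfig, simulate_dataset

config = SimulationConfig(n_samples=120, n_genes=150, n_subgroups=3,
                          signature_genes_per_subgroup=15,
                          loss_subgroup_id=2, seed=3)
dataset, truth = simulate_dataset(config)

result = consensus_select_k(dataset, k_range=range(2, 7), n_iter=15, seed=0)

print("K selection frequency:", dict(sorted(result.k_frequency.items())))
print("chosen K:", result.chosen_K)
print(f"membership consistency: {result.membership_consistency:.3f}")
print(f"adjusted Rand index vs planted labels: "
      f"{adjusted_rand_score(truth.labels, result.labels):.3f}")
# consistency near 1 means resampled runs keep co-clustering the same
# samples; ARI 1.0 means the planted partition was recovered exactly
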