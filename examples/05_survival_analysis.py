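"""Outcome analysis of molecular subgroups: Kaplan-Meier medians,
global log-rank, and a multivariate Cox model showing the high-risk
subgroup is prognostic independent of stage."""

import numpy as np
import pandas as pd

from omicsub import survival as sv
from omicsub.simulate import SimulationConfig, simulate_dataset, simulate_survival

config = SimulationConfig(n_samples=300, n_genes=120, n_subgroups=3,
                          signature_genes_per_subgroup=12,
                          loss_subgroup_id=2, seed=6)
dataset, truth = simulate_dataset(config)
clinical = simulate_survival(truth, config)
labels = truth.labels

for c in np.unique(labels):
    curve = sv.km_estimate(clinical.time[labels == c],
                           clinical.event[labels == c])
    med = f"{curve.median:.0f} months" if np.isfinite(curve.median) else "not reached"
    print(f"cluster {c}: n={np.sum(labels == c)}, median survival {med}")

chi2, df, p = sv.logrank_global(labels, clinical.time, clinical.event)
print(f"\nglobal log-rank: chi2={chi2:.1f} (df={df}), p={p:.2g}")

covs = pd.DataFrame({
    "high_risk_subgroup": (labels == config.loss_subgroup_id).astype(float),
    "iss_3": (clinical.data["iss_stage"] == 3).astype(float).to_numpy(),
})
cox = sv.cox_ph(covs, clinical.time, clinical.event)
print("\nCox proportional hazards (Breslow partial likelihood):")
print(cox.round(3))
# the subgroup's hazard ratio stays well above 1 with ISS stage in the
# model: the molecular segment carries prognosis beyond clinical stage
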