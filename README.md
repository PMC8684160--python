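# omicsub

Integrative multi-omics subtyping of tumor cohorts, built around the
workflow that identifies a high-risk multiple myeloma segment defined
by broad genomic loss: simulate multi-omics cohorts with planted
subgroup structure, recover subgroups by penalized latent-factor
integrative clustering with resampled consensus model selection,
characterize them (marker enrichment, genomic-loss burden, survival),
train a transferable subgroup classifier, and rank master regulators by
regulon enrichment.

It is aimed at computational biologists who want a tested, reusable
implementation of this analysis style — every stage runs end-to-end on
synthetic cohorts with known ground truth, so each statistic can be
validated against its construction.

## The model

Each omics layer *t* (expression, cytoband copy states, mutations, SV
flags) is tied to a shared latent representation **Z** ∈ ℝ^{n×(K−1)}:

- gaussian layers: x_{it} = α_t + β_t' z_i + ε,  ε ~ N(0, 1)
- binary layers:  logit P(x_{it} = 1) = α_t + β_t' z_i

with a lasso penalty λ_t‖β_t‖₁ on the loadings and a N(0, I) prior on
**Z**. Fitting alternates exact penalized regression updates of
(α_t, β_t) with backtracking gradient ascent on **Z**, so the penalized
objective is non-decreasing. Samples are clustered by k-means on **Z**;
K is chosen by resampled consensus: each iteration subsamples 80% of
samples and features, picks the BIC-optimal K, and the modal K across
iterations wins. Final labels cut an average-linkage tree of
1 − consensus, where consensus_{ij} is the co-clustering frequency of
co-sampled pairs.

Around the clustering core:

- **Genomic-loss fraction** — unioned length of loss-called segments ÷
  genome size, the hallmark statistic of the high-risk subgroup.
- **Characterization** — one-vs-rest Fisher / Welch tests with BH-FDR,
  moderated differential expression, weighted Kolmogorov–Smirnov
  gene-set enrichment, GSVA-style single-sample signature scores with
  top-fraction high-risk calls.
- **Survival** — Kaplan–Meier, global log-rank, Cox proportional
  hazards (Newton–Raphson on the Breslow partial likelihood).
- **Classifier** — multinomial lasso on high-variance genes with
  cross-validated gene selection; datasets are harmonized by
  per-dataset, per-gene median/SD scaling before prediction.
- **Master regulators** — aREA/msVIPER-style scoring: signature ranks
  are mapped to normal quantiles and each regulon's NES is the weighted,
  mode-signed target mean times √n_eff, N(0,1) under the null.

## Worked example

`examples/03_integrative_clustering.py` simulates a 120-sample cohort
with 3 planted subgroups and runs consensus clustering:

```
K selection frequency: {3: 15}
chosen K: 3
membership consistency: 1.000
adjusted Rand index vs planted labels: 1.000
```

All 15 resampling iterations vote for K=3, resampled runs co-cluster
the same samples every time (consistency 1.0), and the final labels
match the planted partition exactly (ARI 1.0).

`examples/01_simulate_cohort.py` shows the planted genomic-loss
contrast at full cohort scale (500 samples, 12 subgroups):

```
median loss fraction, broad-loss subgroup: 9.3%
median loss fraction, all other samples:  2.7%
```

The other examples cover loss-burden testing, subgroup
characterization, survival, classifier transfer, and master-regulator
ranking; each prints the numbers it computes and a line on what they
mean. A thin CLI covers the shell-friendly entry points:
`omicsub simulate`, `omicsub validate`, `omicsub run`.

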