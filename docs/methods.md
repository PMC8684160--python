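# Methods

## Scope and data model

The package implements an integrative subtyping workflow for bulk
tumor cohorts profiled on four omics layers: gene expression (TPM-like
abundances), copy-number segment calls (loss/neutral/gain), binary
missense-mutation indicators, and binary structural-variant flags
(IgH translocations t(4;14), t(11;14), t(14;16) and a hyperdiploidy
flag), plus a clinical time-to-event table. All layers are aligned on a
shared sample ordering; assembly either rejects mismatched sample sets
or, on request, restricts to their intersection and logs what was
dropped. Copy-number segments are read in the SEG dialect (1-based
inclusive on disk) and held 0-based half-open in memory.

## Preprocessing

Expression is scaled per sample by the geometric mean of three
housekeeping genes, chosen from an 11-gene candidate panel as the three
with the smallest across-sample SD of log2(TPM+1); ties resolve by gene
id. A non-positive housekeeping value is an error rather than silently
pseudocounted, because the scaling factor would be distorted. Gene
ranking for feature selection uses the coefficient of variation on the
TPM scale (SD is scale-dependent; abundance CV is the quantity that
ranks biological variability there), whereas the housekeeping screen
works on the log scale where stability is usually judged. Mutations are
kept at cohort prevalence ≥ 3% (inclusive).

The genomic-loss fraction of a sample is the unioned base-pair length
of its loss-called segments divided by the genome size. Union, not sum:
summing overlapping segments can exceed 1, and the union is the only
interpretation bounded in [0, 1]. Homozygous and heterozygous deletions
carry the same loss call and count equally. Cytoband copy states take
the call covering the majority of a band's bases (uncovered bases are
neutral; exact ties resolve toward the lower copy state).

## Latent-factor integrative clustering

Every layer is regressed on shared latent coordinates Z (n × (K−1))
through its natural link — identity with unit residual variance for
standardized gaussian layers (expression after log2 and per-gene
median/SD scaling; cytoband states centered at the neutral state 2),
logit for binary layers — with a per-layer lasso penalty on the
loadings and a standard-normal prior on Z. The prior is essential, not
cosmetic: without it the model can inflate Z and deflate the loadings
in proportion, the lasso penalty tends to zero along that path, and
sparsity disappears.

Fitting is blockwise maximization of the penalized MAP objective:

- gaussian layers: vectorized lasso coordinate descent shared across
  features (exact update given Z);
- binary layers: proximal gradient with backtracking on the penalized
  logistic objective (monotone by construction);
- Z: gradient ascent with backtracking on likelihood + prior.

Each block increases the joint objective, so the recorded trace is
non-decreasing per outer iteration; the test suite asserts this on
every fit. Convergence is declared at relative objective change below
tolerance; hitting the iteration cap flags the model rather than
raising. Cluster labels come from k-means (20 restarts, seed derived
from the model) on Z.

### Penalty calibration

Per-layer penalties default to a BIC choice on a 10-point log grid at
K=2 with Z fixed at its PCA initialization: for each candidate λ a
single penalized regression update is scored by −2·loglik +
nnz·log n, and the best (sparser on ties) wins. This adapts sparsity to
the layer's information content: an uninformative layer is driven to
(near-)zero loadings, an informative layer keeps the loadings its
likelihood gain pays for. A fixed sparsity target (for example
"keep 10% of loadings") was rejected after it demonstrably destroyed
label recovery on cohorts in which most features are informative:
latent dimensions collapse under the over-strong penalty and the model
can no longer separate subgroups that plain k-means on the same matrix
separates perfectly.

### Choosing the number of clusters

The plain BIC of this model (−2·loglik + d·log n with d = nonzero
loadings + nonzero intercepts) cannot select K by itself: the n×(K−1)
latent coordinates are free parameters it never charges, so every
additional dimension can absorb noise and BIC decreases monotonically
in K. The selector used per consensus iteration is therefore a
clustered BIC: latent coordinates are collapsed to their cluster
centroids, the likelihood is re-evaluated, and the K×(K−1) centroid
entries are added to the parameter count. Splitting a true cluster then
buys almost no likelihood while still paying for a centroid, giving a
genuine interior minimum at the planted K. The plain `bic()` is still
exposed and used where the latent dimension is not in question
(penalty calibration, COCA's per-layer scans).

Consensus model selection runs `n_iter` iterations, each subsampling
80% of samples and 80% of features per layer, scanning K over the
requested range, and recording the selected K and its labels. The modal
K wins (ties to the smaller K); consensus_{ij} = co-clustered count /
co-sampled count; final labels cut an average-linkage tree of
1 − consensus at the chosen K (never-co-sampled pairs sit at the
uninformative distance 0.5); membership consistency is the mean
consensus of each sample with its final co-members (singletons
contribute 1). The cohort-scale default of 1000 iterations over
K = 2..20 is configurable; tests and examples run 6–20 iterations on
reduced cohorts so the whole suite stays in minutes.

### Cluster-of-clusters (COCA)

Each gaussian layer is clustered by a spherical Gaussian-mixture scan
(BIC-selected K; the mixture's marginal likelihood does not over-reward
splitting unstructured data the way the k-means classification
likelihood does, and reg_covar guards component collapse); binary
layers use k-medoids on Jaccard distances with an analogous criterion.
The per-layer scan includes K=1 so a layer with no structure
contributes nothing. Per-layer memberships become a binary indicator
matrix that is clustered with the same consensus procedure; with a
single informative layer COCA reduces to that layer's solution.

## Characterization statistics

One-vs-rest Fisher exact tests (two-sided) cover binary markers, Welch
t-tests cover continuous scores; both are BH-adjusted within each
cluster's feature family. Differential expression is a per-gene
two-group model on log2 expression whose residual variances are shrunk
toward the global mean variance with configurable weight (default 0.5;
weight 0 recovers the plain pooled t). This is a deliberately simple,
testable analogue of moderated-t machinery; the shrinkage target and
weight are fixed rather than estimated from the data.

Gene-set enrichment uses the weighted Kolmogorov–Smirnov running sum
(hits weighted by |stat|^p, default p=1; misses by 1/(N−m)), with a
gene-label permutation null: NES normalizes ES by the mean |null ES| of
the same sign, and the permutation p is bounded below by 1/(n_perm+1).
Single-sample signature scores reuse the same running-sum machinery on
per-sample centered ranks — a rank-order-equivalent simplification of
GSVA's kernel-density transform — so reversing a sample's expression
ordering flips the score's sign exactly; a whole-universe set and a
constant sample both score 0. High-risk calls flag the ⌈n·fraction⌉
top-scoring samples with ties broken by sample id.

## Survival

Kaplan–Meier, the K-group log-rank test (observed − expected events
with hypergeometric variance, df = K−1), and Cox proportional hazards
by Newton–Raphson on the Breslow partial likelihood (step-halving to
keep the likelihood increasing, tolerance 1e-8) are implemented from
their defining risk-set computations and cross-checked in the tests
against lifelines. Breslow rather than Efron tie handling: ties are
rare in continuous simulated months. The KM median convention is the
smallest event time with S(t) ≤ 0.5, undefined (NaN) if never reached.
ISS stage enters Cox models as dummy variables.

## Subgroup classifier

Candidates are the top genes by CV (cohort default 3813, capped by the
matrix); the design matrix is log2(TPM+1) standardized per gene. Each
of `cv_replicates` replicates (default 10) runs a stratified 10-fold
split; a gene gets the replicate's vote when its lasso multinomial
coefficient is nonzero in at least half the fold fits, and genes voted
in ≥ 50% of replicates enter the final ridge-stabilized multinomial
model. Held-out precision/recall per class come from a fresh
cross-validation of the final gene set. Cross-dataset application
standardizes the new dataset per gene before scoring (missing genes
imputed at the post-standardization mean 0, at most half may be
missing), which removes dataset-level location/scale shifts by
construction.

## Master regulators

A subgroup's signature is the per-gene Welch t of cluster vs rest on
log2 expression (zero-variance genes score 0). Signature values are
rank-transformed to standard-normal quantiles q_g = Φ⁻¹(r_g/(N+1));
a regulon's ES is the likelihood-weighted, mode-signed mean of its
targets' quantiles and NES = ES·√n_eff with n_eff = (Σw)²/Σw², standard
normal under exchangeable target ranks. The analytic p is reported next
to a target-shuffling permutation p as a calibration check; regulators
rank by |NES|. Only this one-tail weighted-mean form is implemented —
no two/three-tail combination, shadow or synergy analysis — because it
is the core that drives regulator ranking; regulon inference itself is
out of scope and regulons are inputs.

## Synthetic cohorts

The generator emulates the discovery-cohort geometry: 500 samples, 12
subgroups with jittered-uniform proportions landing in roughly 5–12%,
25 signature genes per subgroup (70% shifted up, 30% down, 1.5 log2
units, Gaussian noise SD 0.6), a 22-chromosome × 10 Mb genome tiled by
8 cytobands per chromosome (220 Mb total) so everything runs at desk
scale, and per-sample loss fractions drawn from Beta distributions
centered at 9.5% for the designated broad-loss subgroup versus 3%
elsewhere. Loss segments are placed by sampling cytobands without
replacement until the target unioned length is reached, the final
segment truncated to hit it exactly — so the planted fraction is exact
by construction and recomputable from the emitted segments. Focal gains,
subgroup-enriched mutations (background 2%, enriched 25%), and
SV-flag rates (hyperdiploidy dominating half the subgroups,
translocations the rest, t(4;14)/t(14;16) enriched in the broad-loss
subgroup) are order-of-magnitude choices, not calibrated to any real
cohort. The 11 housekeeping candidates are included with 10× reduced
noise. Survival is exponential with per-subgroup hazard ratios
(default: 2.5 for the broad-loss subgroup against a 60-month baseline
median), independent censoring at rate 0.3. Each omics layer draws
from its own RNG stream spawned from the master seed, so identical
(config, seed) reproduce bitwise-identical cohorts and resizing one
layer never perturbs another.

What the generator does not emulate: read-level data, allele-specific
or subclonal copy number, linkage or co-mutation structure, batch
effects, non-proportional hazards, and realistic marker prevalences.
Passing tests therefore demonstrate correctness of the statistics and
recovery under the planted model, not performance on real cohorts.

Reduced problem sizes used by the test suite, chosen as the package's
desk-scale defaults: the subgroup-recovery check runs 300 samples, 200
genes (12 signature genes per subgroup — the full-scale default of 25
cannot fit 12 subgroups into 200 genes), a 20-chromosome × 3-band
genome (60 cytobands), 20 consensus iterations over K = 2..16. Most
unit fixtures use 60–150 samples and 2–3 subgroups.

## Numerical conventions and edge cases

- Tie-breaks are deterministic everywhere: lexicographic gene/sample
  ids (housekeeping selection, CV ranking, GSEA ordering, threshold
  calls), lower copy state (cytoband majority), smaller K (modal-K
  ties).
- Zero-SD genes are dropped before standardization and classifier
  training, with a log line; zero-variance genes score 0 in signatures.
- Degenerate enrichment inputs (absent features, both-sides-constant
  scores) are flagged with p = 1 rather than erroring.
- Latent-model non-convergence warns and flags; empty layers are
  skipped with a log line.
- All randomness flows from a single seed through named substreams;
  k-means seeds are derived from the model seed.

## Known limitations

- The latent model fixes gaussian residual variance at 1 (layers are
  standardized); heteroscedastic features are not modeled.
- The clustered-BIC K selector is a pragmatic repair of a real
  degeneracy; it is consistent on the planted model but has no
  finite-sample guarantee on arbitrary data.
- The classifier's gene-selection stability depends on the penalty
  strength (C); the default is reasonable at desk scale but should be
  re-examined for cohort-scale gene universes.
- COCA's per-layer K=1 opt-out makes it robust to unstructured layers
  but means a layer with weak genuine structure may be silently
  excluded.
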