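"""Integrative clustering core.

A penalized latent-factor model in the iCluster+ family: every omics
layer is regressed on a shared set of K-1 latent sample coordinates Z
through its natural link (identity for gaussian layers, logit for
binary layers) with a lasso penalty on the loadings.  Fitting
alternates exact penalized regression updates of the per-layer
parameters (coordinate descent for gaussian layers, proximal gradient
for bernoulli layers) with backtracking gradient ascent on Z, so the
penalized log-likelihood is non-decreasing across outer iterations.

Model selection follows the resampled-consensus recipe: across
iterations that subsample samples and features, the BIC-optimal K is
recorded; the modal K wins, the co-clustering frequencies of co-sampled
pairs form a consensus matrix, and final labels come from
average-linkage clustering of 1 - consensus.  A cluster-of-clusters
(COCA) alternative clusters each layer separately and then clusters the
binary membership-indicator matrix with the same consensus procedure.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .dataio import MultiOmicsDataset
from .preprocess import standardize_genes

logger = logging.getLogger(__name__)

GAUSSIAN = "gaussian"
BERNOULLI = "bernoulli"


@dataclass
class Layer:
    """One omics layer prepared for the latent model: samples x features."""

    name: str
    X: np.ndarray
    family: str
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        if self.family not in (GAUSSIAN, BERNOULLI):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == BERNOULLI and not np.isin(self.X, [0.0, 1.0]).all():
            raise ValueError(f"layer {self.name}: bernoulli layer must be binary")


def prepare_layers(dataset: MultiOmicsDataset) -> list[Layer]:
    """Turn a dataset into model-ready layers.

    Expression becomes gaussian after log2(TPM+1) and per-gene
    median/SD standardization; cytoband copy states are centered at the
    neutral state 2 and treated as gaussian; mutations and SV flags are
    bernoulli.
    """
    layers = []
    expr_std = standardize_genes(np.log2(dataset.expression + 1.0))
    layers.append(Layer("expression", expr_std.to_numpy().T, GAUSSIAN,
                        list(expr_std.index)))
    if dataset.cnv_states is not None:
        layers.append(Layer("cnv", (dataset.cnv_states.to_numpy().T - 2.0),
                            GAUSSIAN, list(dataset.cnv_states.index)))
    if dataset.mutations is not None:
        layers.append(Layer("mutations", dataset.mutations.to_numpy(float).T,
                            BERNOULLI, list(dataset.mutations.index)))
    if dataset.sv_flags is not None:
        layers.append(Layer("sv", dataset.sv_flags.to_numpy(float).T,
                            BERNOULLI, list(dataset.sv_flags.index)))
    return [ly for ly in layers if ly.X.shape[1] > 0]


@dataclass
class LatentFactorModel:
    K: int
    Z: np.ndarray                       # samples x (K-1)
    alphas: dict[str, np.ndarray]       # per-layer intercepts
    betas: dict[str, np.ndarray]        # per-layer loadings, (K-1) x features
    families: dict[str, str]
    lambdas: dict[str, float]
    loglik_trace: list[float]           # penalized objective per outer iteration
    loglik: float                       # final unpenalized log-likelihood
    converged: bool
    seed: int

    def n_nonzero(self) -> int:
        return int(sum(np.count_nonzero(b) for b in self.betas.values()))


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def _layer_loglik(layer: Layer, alpha, beta, Z) -> float:
    eta = alpha[None, :] + Z @ beta
    if layer.family == GAUSSIAN:
        return float(-0.5 * np.sum((layer.X - eta) ** 2))
    return float(np.sum(layer.X * eta - np.logaddexp(0.0, eta)))


def _penalized_objective(layers, alphas, betas, lambdas, Z) -> float:
    """Joint MAP objective: data log-likelihood + standard-normal prior
    on the latent coordinates (which pins the Z/beta scale) - lasso
    penalty on the loadings."""
    total = -0.5 * float(np.sum(Z**2))
    for ly in layers:
        total += _layer_loglik(ly, alphas[ly.name], betas[ly.name], Z)
        total -= lambdas[ly.name] * np.abs(betas[ly.name]).sum()
    return total


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _gaussian_mstep(X, Z, alpha, beta, lam, sweeps=200, tol=1e-9):
    """Vectorized lasso coordinate descent shared across features."""
    n, q = Z.shape
    znorm = (Z**2).sum(axis=0)
    for _ in range(sweeps):
        alpha = (X - Z @ beta).mean(axis=0)
        delta = 0.0
        R = X - alpha[None, :] - Z @ beta
        for j in range(q):
            if znorm[j] == 0:
                continue
            R += np.outer(Z[:, j], beta[j])
            num = Z[:, j] @ R
            new = _soft(num, lam) / znorm[j]
            delta = max(delta, np.max(np.abs(new - beta[j])) if beta[j].size else 0.0)
            beta[j] = new
            R -= np.outer(Z[:, j], beta[j])
        if delta < tol:
            break
    alpha = (X - Z @ beta).mean(axis=0)
    return alpha, beta


def _bernoulli_mstep(X, Z, alpha, beta, lam, max_iter=300, tol=1e-8):
    """Proximal gradient (with backtracking) on the penalized logistic
    objective, vectorized across features."""
    n, q = Z.shape

    def neg_ll(a, b):
        eta = a[None, :] + Z @ b
        return float(np.sum(np.logaddexp(0.0, eta) - X * eta))

    step = 4.0 / (np.linalg.norm(Z, ord="fro") ** 2 / Z.shape[1] + n + 1e-12)
    f = neg_ll(alpha, beta)
    for _ in range(max_iter):
        eta = alpha[None, :] + Z @ beta
        P = 1.0 / (1.0 + np.exp(-eta))
        g_alpha = (P - X).sum(axis=0)
        g_beta = Z.T @ (P - X)
        for _bt in range(50):
            a_new = alpha - step * g_alpha
            b_new = _soft(beta - step * g_beta, step * lam)
            da, db = a_new - alpha, b_new - beta
            quad = (f + np.sum(g_alpha * da) + np.sum(g_beta * db)
                    + (np.sum(da**2) + np.sum(db**2)) / (2.0 * step))
            f_new = neg_ll(a_new, b_new)
            if f_new <= quad + 1e-10:
                break
            step /= 2.0
        improve = (f + lam * np.abs(beta).sum()) - (f_new + lam * np.abs(b_new).sum())
        alpha, beta, f = a_new, b_new, f_new
        step *= 1.5  # cautious step recovery
        if 0 <= improve < tol * (abs(f) + 1.0):
            break
    return alpha, beta


def _z_step(layers, alphas, betas, Z, max_iter=25, tol=1e-9):
    """Backtracking gradient ascent in Z on log-likelihood + N(0,1) prior."""

    def loglik(Zc):
        return sum(_layer_loglik(ly, alphas[ly.name], betas[ly.name], Zc)
                   for ly in layers) - 0.5 * float(np.sum(Zc**2))

    ll = loglik(Z)
    step = 1.0 / (sum(np.linalg.norm(betas[ly.name], ord="fro") ** 2
                      for ly in layers) + 1.0)
    for _ in range(max_iter):
        grad = -Z
        for ly in layers:
            eta = alphas[ly.name][None, :] + Z @ betas[ly.name]
            if ly.family == GAUSSIAN:
                resid = ly.X - eta
            else:
                resid = ly.X - 1.0 / (1.0 + np.exp(-eta))
            grad += resid @ betas[ly.name].T
        improved = False
        for _bt in range(40):
            Z_new = Z + step * grad
            ll_new = loglik(Z_new)
            if ll_new >= ll:
                improved = True
                break
            step /= 2.0
        if not improved:
            break
        gain = ll_new - ll
        Z, ll = Z_new, ll_new
        step *= 1.5
        if gain < tol * (abs(ll) + 1.0):
            break
    return Z, ll


def _init_z(layers, q, seed) -> np.ndarray:
    """Principal components of the concatenated (centered) layers."""
    blocks = []
    for ly in layers:
        Xc = ly.X - ly.X.mean(axis=0, keepdims=True)
        blocks.append(Xc)
    concat = np.hstack(blocks)
    # randomized fallback keeps degenerate inputs full rank
    rng = np.random.default_rng(seed)
    concat = concat + 1e-10 * rng.standard_normal(concat.shape)
    U, s, _ = np.linalg.svd(concat, full_matrices=False)
    n_avail = min(q, U.shape[1])
    Z = U[:, :n_avail] * s[:n_avail]
    if n_avail < q:  # fewer features than latent dims: random completion
        Z = np.hstack([Z, rng.standard_normal((Z.shape[0], q - n_avail))])
    sd = Z.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return Z / sd


def fit_latent_model(
    layers: list[Layer] | MultiOmicsDataset,
    K: int,
    lambdas: dict[str, float] | float = 1.0,
    max_iter: int = 30,
    tol: float = 1e-6,
    seed: int = 0,
) -> LatentFactorModel:
    """Fit the penalized latent-factor model with K clusters (K-1 factors).

    ``lambdas`` is the per-layer lasso penalty (a scalar applies to all
    layers).  The penalized objective is recorded per outer iteration
    and is non-decreasing; non-convergence within ``max_iter`` flags the
    model rather than raising.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if isinstance(layers, MultiOmicsDataset):
        layers = prepare_layers(layers)
    layers = [ly for ly in layers if ly.X.shape[1] > 0]
    if not layers:
        raise ValueError("no non-empty layers")
    if not isinstance(lambdas, dict):
        lambdas = {ly.name: float(lambdas) for ly in layers}
    q = K - 1
    Z = _init_z(layers, q, seed)
    alphas = {ly.name: ly.X.mean(axis=0) for ly in layers}
    betas = {ly.name: np.zeros((q, ly.X.shape[1])) for ly in layers}

    trace = []
    converged = False
    for it in range(max_iter):
        for ly in layers:
            if ly.family == GAUSSIAN:
                alphas[ly.name], betas[ly.name] = _gaussian_mstep(
                    ly.X, Z, alphas[ly.name], betas[ly.name], lambdas[ly.name]
                )
            else:
                alphas[ly.name], betas[ly.name] = _bernoulli_mstep(
                    ly.X, Z, alphas[ly.name], betas[ly.name], lambdas[ly.name]
                )
        Z, _ = _z_step(layers, alphas, betas, Z)
        obj = _penalized_objective(layers, alphas, betas, lambdas, Z)
        trace.append(obj)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            converged = True
            break
    if not converged:
        warnings.warn(f"latent model (K={K}) did not converge in {max_iter} iterations")
    loglik = sum(_layer_loglik(ly, alphas[ly.name], betas[ly.name], Z)
                 for ly in layers)
    return LatentFactorModel(
        K=K, Z=Z, alphas=alphas, betas=betas,
        families={ly.name: ly.family for ly in layers},
        lambdas=dict(lambdas), loglik_trace=trace, loglik=loglik,
        converged=converged, seed=seed,
    )


def assign_clusters(model: LatentFactorModel) -> np.ndarray:
    """K-means on the latent coordinates; deterministic given the model."""
    Z = model.Z
    if np.allclose(Z.std(axis=0), 0):
        raise ValueError("degenerate latent space: zero variance in Z")
    km = KMeans(n_clusters=model.K, n_init=20,
                random_state=(model.seed * 7919 + model.K) % (2**31))
    return km.fit_predict(Z)


def bic(model: LatentFactorModel, layers=None) -> float:
    """-2 loglik + d log(n) with d = nonzero loadings + nonzero intercepts."""
    n = model.Z.shape[0]
    d = model.n_nonzero() + int(
        sum(np.count_nonzero(a) for a in model.alphas.values())
    )
    return float(-2.0 * model.loglik + d * np.log(n))


def clustered_bic(model: LatentFactorModel, layers: list[Layer],
                  labels: np.ndarray) -> float:
    """BIC of the clustered model: latent coordinates collapsed to their
    cluster centroids.

    The free per-sample latent coordinates are not charged by the plain
    BIC, so it decreases monotonically in K once extra dimensions start
    absorbing noise.  Replacing each sample's coordinates by its
    cluster centroid makes the cluster structure itself carry the
    likelihood: parameters are the nonzero loadings and intercepts plus
    the K x (K-1) centroid entries, and splitting a true cluster no
    longer pays.  This is the criterion used to select K per
    consensus iteration.
    """
    K = model.K
    cent = np.vstack([
        model.Z[labels == k].mean(axis=0) if np.any(labels == k)
        else np.zeros(model.Z.shape[1])
        for k in range(K)
    ])
    Zc = cent[labels]
    ll = sum(_layer_loglik(ly, model.alphas[ly.name], model.betas[ly.name], Zc)
             for ly in layers)
    n = model.Z.shape[0]
    d = model.n_nonzero() + int(
        sum(np.count_nonzero(a) for a in model.alphas.values())
    ) + K * (K - 1)
    return float(-2.0 * ll + d * np.log(n))


# ---------------------------------------------------------------------------
# penalty calibration
# ---------------------------------------------------------------------------


def calibrate_penalties(
    layers: list[Layer],
    K: int = 2,
    seed: int = 0,
    n_grid: int = 10,
) -> dict[str, float]:
    """Choose a per-layer lasso penalty by BIC on a log-spaced grid.

    The latent coordinates are fixed at their principal-component
    initialization and a single penalized regression update is run per
    candidate penalty; the per-layer BIC (-2 loglik + nonzero-loadings
    * log n) picks the penalty, preferring the stronger penalty on
    ties.  This adapts sparsity to the layer: a noise layer drives the
    penalty up until its loadings vanish, an informative layer keeps
    the loadings its likelihood gain pays for.  Cheap, deterministic,
    and close enough to the full fit for model-selection purposes.
    """
    q = K - 1
    Z = _init_z(layers, q, seed)
    n = Z.shape[0]
    out = {}
    for ly in layers:
        p = ly.X.shape[1]
        Xc = ly.X - ly.X.mean(axis=0, keepdims=True)
        lam_max = float(np.max(np.abs(Z.T @ Xc))) + 1e-9
        grid = np.geomspace(lam_max, lam_max * 1e-3, n_grid)
        best = None
        for lam in grid:
            alpha = ly.X.mean(axis=0).copy()
            beta = np.zeros((q, p))
            if ly.family == GAUSSIAN:
                alpha, beta = _gaussian_mstep(ly.X, Z, alpha, beta, lam, sweeps=50)
            else:
                alpha, beta = _bernoulli_mstep(ly.X, Z, alpha, beta, lam, max_iter=100)
            ll = _layer_loglik(ly, alpha, beta, Z)
            b = -2.0 * ll + np.count_nonzero(beta) * np.log(n)
            if best is None or b < best[0] - 1e-9:
                best = (b, float(lam))
        out[ly.name] = best[1]
    return out


# ---------------------------------------------------------------------------
# consensus model selection
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    consensus: np.ndarray
    co_sampled_counts: np.ndarray
    k_frequency: dict[int, int]
    chosen_K: int
    membership_consistency: float
    labels: np.ndarray
    sample_ids: list[str] | None = None


def consensus_select_k(
    dataset: MultiOmicsDataset | list[Layer],
    k_range=range(2, 21),
    n_iter: int = 100,
    sample_frac: float = 0.8,
    feature_frac: float = 0.8,
    lambdas: dict[str, float] | float | None = None,
    max_iter: int = 15,
    seed: int = 0,
) -> ConsensusResult:
    """Resampled consensus clustering with BIC selection of K.

    Each iteration subsamples samples and per-layer features, fits the
    latent model across ``k_range``, and records the BIC-optimal K and
    its labels.  The modal K across iterations (ties to the smaller K)
    is chosen; consensus[i, j] is the co-clustering frequency of
    co-sampled pairs, final labels cut an average-linkage tree of
    1 - consensus at the chosen K, and membership consistency is the
    mean consensus of each sample with its final co-members.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0 < sample_frac <= 1 and 0 < feature_frac <= 1):
        raise ValueError("resampling fractions must be in (0, 1]")
    sample_ids = None
    if isinstance(dataset, MultiOmicsDataset):
        sample_ids = dataset.sample_ids
        layers = prepare_layers(dataset)
    else:
        layers = dataset
    n = layers[0].X.shape[0]
    k_range = list(k_range)
    if lambdas is None:
        lambdas = calibrate_penalties(layers, K=min(k_range), seed=seed)
        logger.info("calibrated penalties: %s", lambdas)
    elif not isinstance(lambdas, dict):
        lambdas = {ly.name: float(lambdas) for ly in layers}

    co_clustered = np.zeros((n, n))
    co_sampled = np.zeros((n, n))
    k_counts: Counter[int] = Counter()
    seeds = np.random.SeedSequence(seed).spawn(n_iter)
    n_sub = max(int(round(sample_frac * n)), 2)
    for it in range(n_iter):
        rng = np.random.default_rng(seeds[it])
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        if n_sub < max(k_range):
            logger.info("iteration %d skipped: subset smaller than K", it)
            continue
        sub_layers = []
        for ly in layers:
            p = ly.X.shape[1]
            fsub = np.sort(rng.choice(p, size=max(int(round(feature_frac * p)), 1),
                                      replace=False))
            sub_layers.append(Layer(ly.name, ly.X[np.ix_(idx, fsub)], ly.family))
        fits = []
        it_seed = int(seeds[it].generate_state(1)[0] % (2**31))
        for K in k_range:
            if K >= n_sub:
                continue
            model = fit_latent_model(sub_layers, K, lambdas, max_iter=max_iter,
                                     tol=1e-5, seed=it_seed)
            lab_K = assign_clusters(model)
            fits.append((clustered_bic(model, sub_layers, lab_K), K, lab_K))
        if not fits:
            continue
        _, K_star, labels = min(fits, key=lambda f: (f[0], f[1]))
        k_counts[K_star] += 1
        same = labels[:, None] == labels[None, :]
        co_clustered[np.ix_(idx, idx)] += same
        co_sampled[np.ix_(idx, idx)] += 1

    if not k_counts:
        raise RuntimeError("no successful consensus iteration")
    max_count = max(k_counts.values())
    chosen_K = min(k for k, c in k_counts.items() if c == max_count)

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sampled > 0, co_clustered / co_sampled, np.nan)
    # pairs never co-sampled are uninformative: neutral 0.5 for clustering
    dist = 1.0 - np.nan_to_num(consensus, nan=0.5)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = average(condensed)
    labels = fcluster(tree, t=chosen_K, criterion="maxclust") - 1

    cons_filled = np.nan_to_num(consensus, nan=0.0)
    consistencies = []
    for i in range(n):
        mates = np.nonzero((labels == labels[i]) & (np.arange(n) != i))[0]
        consistencies.append(cons_filled[i, mates].mean() if mates.size else 1.0)
    return ConsensusResult(
        consensus=consensus,
        co_sampled_counts=co_sampled,
        k_frequency=dict(k_counts),
        chosen_K=chosen_K,
        membership_consistency=float(np.mean(consistencies)),
        labels=labels,
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# cluster-of-clusters (COCA)
# ---------------------------------------------------------------------------


@dataclass
class ClusterSolution:
    labels: np.ndarray
    K: int
    bic: float
    loglik: float


def _gaussian_layer_bic(X: np.ndarray, K: int, seed: int) -> tuple[np.ndarray, float]:
    """Spherical gaussian-mixture BIC: the marginal (soft-assignment)
    likelihood does not over-reward splitting unstructured data the way
    the k-means classification likelihood does.  reg_covar guards
    against component collapse at larger K."""
    gm = GaussianMixture(n_components=K, covariance_type="spherical",
                         n_init=3, reg_covar=1e-2,
                         random_state=seed % (2**31))
    labels = gm.fit_predict(X)
    return labels, float(gm.bic(X))


def _kmedoids(D: np.ndarray, K: int, rng: np.random.Generator,
              max_iter: int = 50) -> np.ndarray:
    n = D.shape[0]
    medoids = rng.choice(n, size=K, replace=False)
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for k in range(K):
            members = np.nonzero(labels == k)[0]
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[k] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _binary_layer_solution(X: np.ndarray, k_range, rng) -> tuple[np.ndarray, int]:
    D = squareform(pdist(X, metric="jaccard"))
    n = X.shape[0]
    best = None
    for K in k_range:
        if K >= n:
            continue
        labels = np.zeros(n, dtype=int) if K == 1 else _kmedoids(D, K, rng)
        w = np.array([D[i, :][labels == labels[i]].sum() for i in range(n)]).sum()
        sigma2 = max(w / n, 1e-12)
        ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        b = -2.0 * ll + (K + 1) * np.log(n)
        if best is None or b < best[0]:
            best = (b, K, labels)
    return best[2], best[1]


def coca(
    dataset: MultiOmicsDataset | list[Layer],
    k_range=range(2, 21),
    n_iter: int = 50,
    seed: int = 0,
) -> ClusterSolution:
    """Two-step cluster-of-clusters: per-layer clustering, then
    consensus clustering of the binary membership-indicator matrix."""
    if isinstance(dataset, MultiOmicsDataset):
        layers = prepare_layers(dataset)
    else:
        layers = dataset
    # per-layer scan includes K=1 so an unstructured layer can opt out of
    # contributing indicator columns
    k_scan = sorted(set([1] + list(k_range)))
    k_range = list(k_range)
    rng = np.random.default_rng(seed)
    per_layer: list[tuple[np.ndarray, int]] = []
    for ly in layers:
        if ly.family == GAUSSIAN:
            best = None
            for K in k_scan:
                if K >= ly.X.shape[0]:
                    continue
                labels, b = _gaussian_layer_bic(ly.X, K, seed + K)
                if best is None or b < best[0]:
                    best = (b, K, labels)
            per_layer.append((best[2], best[1]))
        else:
            per_layer.append(_binary_layer_solution(ly.X, k_scan, rng))
    if len(per_layer) == 1:
        labels, K = per_layer[0]
        return ClusterSolution(labels=labels, K=K, bic=float("nan"),
                               loglik=float("nan"))
    blocks = []
    for labels, K in per_layer:
        if K == 1:
            logger.info("a layer selected a single cluster; it contributes "
                        "no indicator columns")
            continue
        ind = np.zeros((len(labels), K))
        ind[np.arange(len(labels)), labels] = 1.0
        blocks.append(ind)
    if not blocks:
        n = len(per_layer[0][0])
        return ClusterSolution(labels=np.zeros(n, dtype=int), K=1,
                               bic=float("nan"), loglik=float("nan"))
    indicator = np.hstack(blocks)
    ind_layer = Layer("coca_indicator", indicator, BERNOULLI)
    res = consensus_select_k([ind_layer], k_range=k_range, n_iter=n_iter,
                             seed=seed)
    return ClusterSolution(labels=res.labels, K=res.chosen_K,
                           bic=float("nan"), loglik=float("nan"))
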