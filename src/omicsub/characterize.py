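"""Per-subgroup molecular characterization.

One-vs-rest Fisher tests for binary markers (mutations, CNV and SV
indicators), Welch t-tests for continuous pathway scores, moderated
two-group differential expression, weighted Kolmogorov-Smirnov gene-set
enrichment with a permutation null, single-sample rank-based signature
scores, and top-fraction thresholding of signature scores into
high-risk calls.  All p-values are Benjamini-Hochberg adjusted within
their feature family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# one-vs-rest enrichment
# ---------------------------------------------------------------------------


def enrich_binary(labels, binary: pd.DataFrame) -> pd.DataFrame:
    """Fisher exact one-vs-rest enrichment of binary features.

    For every cluster and feature, a two-sided Fisher exact test on the
    2x2 carrier table; q is BH-adjusted within each cluster's feature
    family.  Features absent everywhere get p=1 and an undefined odds
    ratio, flagged in the ``degenerate`` column.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for c in clusters:
        inside = labels == c
        for feat in binary.index:
            x = binary.loc[feat].to_numpy()
            a = int(x[inside].sum())
            b = int(inside.sum()) - a
            d = int(x[~inside].sum())
            e = int((~inside).sum()) - d
            degenerate = (a + d) == 0
            if degenerate:
                orat, p = np.nan, 1.0
            else:
                orat, p = sps.fisher_exact([[a, b], [d, e]], alternative="two-sided")
            direction = "up" if (a / max(inside.sum(), 1)) >= (d / max((~inside).sum(), 1)) else "down"
            rows.append((c, feat, orat, p, direction, degenerate))
    out = pd.DataFrame(rows, columns=["cluster", "feature", "odds_ratio", "p",
                                      "direction", "degenerate"])
    out["q"] = np.concatenate([
        bh_fdr(out.loc[out["cluster"] == c, "p"]) for c in clusters
    ])
    return out


def enrich_continuous(labels, scores: pd.DataFrame) -> pd.DataFrame:
    """Welch t one-vs-rest enrichment of continuous per-sample scores."""
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters")
    rows = []
    for c in clusters:
        inside = labels == c
        if inside.sum() < 2 or (~inside).sum() < 2:
            raise ValueError(f"cluster {c}: need >= 2 samples on each side")
        for feat in scores.index:
            x = scores.loc[feat].to_numpy(float)
            xin, xout = x[inside], x[~inside]
            degenerate = xin.std(ddof=1) == 0 and xout.std(ddof=1) == 0
            if degenerate:
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(xin, xout, equal_var=False)
            rows.append((c, feat, t, p, "up" if t >= 0 else "down", degenerate))
    out = pd.DataFrame(rows, columns=["cluster", "feature", "t", "p",
                                      "direction", "degenerate"])
    out["q"] = np.concatenate([
        bh_fdr(out.loc[out["cluster"] == c, "p"]) for c in clusters
    ])
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def differential_expression(
    expr_log2: pd.DataFrame,
    labels,
    cluster,
    shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-group differential expression, cluster vs rest.

    Per gene, a two-group linear model on log2 expression; residual
    variances are shrunk toward the global mean variance with weight
    ``shrinkage`` (0 recovers the plain pooled-variance t).  Returns a
    per-gene table with log-fold-change, t, p, q and a significance flag
    at q < 0.05.
    """
    labels = np.asarray(labels)
    inside = labels == cluster
    n1, n0 = int(inside.sum()), int((~inside).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each side needs >= 2 samples")
    X = expr_log2.to_numpy(float)
    m1 = X[:, inside].mean(axis=1)
    m0 = X[:, ~inside].mean(axis=1)
    v1 = X[:, inside].var(axis=1, ddof=1)
    v0 = X[:, ~inside].var(axis=1, ddof=1)
    df = n1 + n0 - 2
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    shrunk = (1.0 - shrinkage) * pooled + shrinkage * pooled.mean()
    lfc = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(shrunk * (1.0 / n1 + 1.0 / n0))
    t = np.where(shrunk == 0, 0.0, t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"lfc": lfc, "t": t, "p": p, "q": q, "significant": q < 0.05},
        index=expr_log2.index,
    )


# ---------------------------------------------------------------------------
# weighted KS enrichment machinery
# ---------------------------------------------------------------------------


def _running_sum_es(ordered_stats: np.ndarray, is_hit: np.ndarray, p: float) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``ordered_stats`` must already be sorted in ranking order.  Hits
    increment by |stat|^p normalized over the set; misses decrement by
    1/(N - m).
    """
    n = len(ordered_stats)
    m = int(is_hit.sum())
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    w = np.abs(ordered_stats) ** p
    hit_total = w[is_hit].sum()
    if hit_total == 0:  # all hit weights zero: fall back to unweighted
        incr = np.where(is_hit, 1.0 / m, 0.0)
    else:
        incr = np.where(is_hit, w / hit_total, 0.0)
    decr = np.where(is_hit, 0.0, 1.0 / (n - m))
    running = np.cumsum(incr - decr)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


@dataclass
class GseaResult:
    es: float
    nes: float
    p: float
    q: float
    n_genes: int


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Weighted KS enrichment of a gene set in a ranked statistic.

    Genes are ordered by decreasing statistic (ties broken by gene id).
    The null is gene-label permutation: ``n_perm`` random sets of the
    same size.  NES normalizes ES by the mean |null ES| of the same
    sign; the permutation p is bounded below by 1/(n_perm + 1).
    """
    stats_sorted = ranked_stats.sort_index().sort_values(
        ascending=False, kind="mergesort"
    )
    universe = list(stats_sorted.index)
    requested = set(gene_set)
    present = requested & set(universe)
    if not present:
        raise ValueError("gene set empty after restriction to the universe")
    if len(present) == len(universe):
        raise ValueError("gene set equals the ranking universe")
    values = stats_sorted.to_numpy(float)
    is_hit = np.isin(np.array(universe), list(present))
    es = _running_sum_es(values, is_hit, weight)

    rng = np.random.default_rng(seed)
    m = int(is_hit.sum())
    null_es = np.empty(n_perm)
    idx = np.arange(len(universe))
    for b in range(n_perm):
        hit = np.zeros(len(universe), dtype=bool)
        hit[rng.choice(idx, size=m, replace=False)] = True
        null_es[b] = _running_sum_es(values, hit, weight)
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    more_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p = (1 + more_extreme) / (1 + n_same) if n_same else 1.0
    denom = np.abs(null_es[same_sign]).mean() if n_same else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
    return GseaResult(es=es, nes=nes, p=p, q=p, n_genes=m)


def gsea_collection(
    ranked_stats: pd.Series,
    gene_sets: dict,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`gsea_preranked` over a GMT collection with BH-FDR across sets."""
    rows = {}
    for i, (name, genes) in enumerate(gene_sets.items()):
        try:
            res = gsea_preranked(ranked_stats, genes, weight=weight,
                                 n_perm=n_perm, seed=seed + i)
        except ValueError:
            continue
        rows[name] = res
    out = pd.DataFrame(
        {
            "es": {k: r.es for k, r in rows.items()},
            "nes": {k: r.nes for k, r in rows.items()},
            "p": {k: r.p for k, r in rows.items()},
            "n_genes": {k: r.n_genes for k, r in rows.items()},
        }
    )
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    return out


# ---------------------------------------------------------------------------
# single-sample signature scores
# ---------------------------------------------------------------------------


def signature_score(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Rank-based single-sample enrichment score of a gene set.

    Per sample, genes are ranked by expression; the score is the signed
    maximum deviation of the weighted KS running sum using centered
    ranks as the statistic, so reversing a sample's expression ordering
    flips the score's sign.  A constant expression column scores 0.
    """
    present = [g for g in expr.index if g in set(gene_set)]
    if not present:
        raise ValueError("gene set does not intersect the expression matrix")
    n = expr.shape[0]
    hit_mask = expr.index.isin(present)
    if hit_mask.all():
        return pd.Series(0.0, index=expr.columns)
    scores = {}
    gene_order = np.argsort(expr.index.to_numpy())  # id tie-break
    for sample in expr.columns:
        x = expr[sample].to_numpy(float)
        if np.allclose(x, x[0]):
            scores[sample] = 0.0
            continue
        ranks = sps.rankdata(x, method="average")
        centered = ranks - (n + 1) / 2.0
        order = np.lexsort((gene_order, -centered))
        scores[sample] = _running_sum_es(centered[order], hit_mask[order], 1.0)
    return pd.Series(scores, name="signature_score")


def signature_threshold(scores: pd.Series, top_fraction: float) -> pd.Series:
    """Flag the ceil(n * top_fraction) highest-scoring samples.

    Ties at the cutoff are broken by sample id so the flag set is
    deterministic.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    n_flag = int(np.ceil(len(scores) * top_fraction))
    order = sorted(scores.index, key=lambda s: (-scores[s], s))
    flagged = set(order[:n_flag])
    return pd.Series({s: int(s in flagged) for s in scores.index},
                     name="high_score")
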