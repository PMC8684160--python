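"""Subgroup classifier transferable across expression datasets.

A multinomial lasso (optionally elastic-net) model on standardized
expression of high-variance genes.  Gene selection is stabilized by
repeated cross-validation: genes with nonzero coefficients in a
majority of replicate fits enter the final multinomial model.  New
datasets are harmonized by per-dataset, per-gene median/SD scaling on
the shared gene universe before prediction, so dataset-level location
and scale shifts cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .preprocess import select_high_variance, standardize_genes

logger = logging.getLogger(__name__)


@dataclass
class SubgroupClassifier:
    genes: list[str]
    classes: list
    coefficients: np.ndarray          # classes x genes
    intercepts: np.ndarray            # classes
    cv_metrics: pd.DataFrame | None = field(default=None, repr=False)
    selection_counts: pd.Series | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Plain-text, diffable coefficient table (genes x classes,
        intercept as the last row)."""
        df = pd.DataFrame(self.coefficients.T, index=self.genes,
                          columns=[str(c) for c in self.classes])
        df.loc["(intercept)"] = self.intercepts
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubgroupClassifier":
        intercepts = df.loc["(intercept)"].to_numpy(float)
        genes = [g for g in df.index if g != "(intercept)"]
        return cls(genes=genes, classes=list(df.columns),
                   coefficients=df.loc[genes].to_numpy(float).T,
                   intercepts=intercepts)


def _log_standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM+1) then per-gene median/SD scaling."""
    return standardize_genes(np.log2(expr + 1.0))


def harmonize(datasets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge expression datasets on their shared gene universe.

    Each dataset is scaled independently per gene to median 0 / SD 1,
    then all are concatenated on the intersection of gene sets.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    scaled = [_log_standardize(d) for d in datasets]
    common = set(scaled[0].index)
    for d in scaled[1:]:
        common &= set(d.index)
    if not common:
        raise ValueError("empty gene intersection across datasets")
    genes = [g for g in scaled[0].index if g in common]
    return pd.concat([d.loc[genes] for d in scaled], axis=1)


def train_classifier(
    expr: pd.DataFrame,
    labels,
    n_candidate_genes: int = 3813,
    cv_replicates: int = 10,
    n_folds: int = 10,
    selection_frac: float = 0.5,
    mixing: float = 1.0,
    C: float = 0.5,
    seed: int = 0,
) -> SubgroupClassifier:
    """Train the multinomial subgroup classifier.

    expr is a TPM-like genes x samples matrix.  The candidate pool is
    the top ``n_candidate_genes`` by coefficient of variation; each of
    ``cv_replicates`` replicates runs an ``n_folds``-fold penalized
    multinomial fit (lasso at ``mixing``=1, elastic-net otherwise) and
    votes for genes with nonzero coefficients in a majority of its
    folds.  Genes voted for in >= ``selection_frac`` of replicates are
    refit in the final model; held-out per-class precision/recall of
    the final gene set is reported from a fresh cross-validation.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    if counts.min() < 5:
        small = classes[counts < 5].tolist()
        raise ValueError(f"classes with < 5 samples: {small}")
    sds = expr.std(axis=1, ddof=1)
    if (sds == 0).any():
        logger.info("excluding %d zero-variance genes", int((sds == 0).sum()))
        expr = expr.loc[sds > 0]
    n_cand = min(n_candidate_genes, expr.shape[0])
    candidates = select_high_variance(expr, n_cand)
    X = _log_standardize(expr.loc[candidates]).T  # samples x genes
    candidates = list(X.columns)
    n_folds_eff = min(n_folds, int(counts.min()))

    penalty = "l1" if mixing >= 1.0 else "elasticnet"
    kwargs = {"penalty": penalty, "C": C, "solver": "saga", "max_iter": 3000,
              "tol": 1e-4}
    if penalty == "elasticnet":
        kwargs["l1_ratio"] = mixing

    votes = pd.Series(0, index=candidates, dtype=int)
    for r in range(cv_replicates):
        skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True,
                              random_state=seed + r)
        fold_nonzero = np.zeros(len(candidates))
        for train_idx, _ in skf.split(X, labels):
            clf = LogisticRegression(random_state=seed + r, **kwargs)
            clf.fit(X.iloc[train_idx], labels[train_idx])
            fold_nonzero += (np.abs(clf.coef_).max(axis=0) > 1e-10)
        votes += (fold_nonzero >= n_folds_eff / 2.0).astype(int)
    kept = [g for g in candidates if votes[g] >= selection_frac * cv_replicates]
    if not kept:
        raise ValueError(
            "no gene survived cross-validated selection; lower the penalty "
            "(increase C) or the selection fraction"
        )
    logger.info("selected %d genes across %d replicates", len(kept), cv_replicates)

    Xk = X[kept]
    final = LogisticRegression(penalty="l2", C=10.0, solver="lbfgs",
                               max_iter=5000, random_state=seed)
    final.fit(Xk, labels)

    # held-out metrics of the final gene set
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    pred = np.empty(len(labels), dtype=labels.dtype)
    for train_idx, test_idx in skf.split(Xk, labels):
        m = LogisticRegression(penalty="l2", C=10.0, solver="lbfgs",
                               max_iter=5000, random_state=seed)
        m.fit(Xk.iloc[train_idx], labels[train_idx])
        pred[test_idx] = m.predict(Xk.iloc[test_idx])
    metrics = _precision_recall(pred, labels, classes)

    coef, intercept = final.coef_, final.intercept_
    if coef.shape[0] == 1:  # binary fit: expand to two-row softmax form
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
        intercept = np.array([0.0, intercept[0]])
    return SubgroupClassifier(
        genes=kept,
        classes=list(final.classes_),
        coefficients=coef,
        intercepts=intercept,
        cv_metrics=metrics,
        selection_counts=votes[kept],
    )


def predict(classifier: SubgroupClassifier, expr: pd.DataFrame
            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the classifier to a TPM-like expression matrix.

    The input is standardized per gene within the dataset; classifier
    genes missing from it are imputed as 0 (the post-standardization
    mean) with a log message, but at least half must be present.
    Returns (labels, class-probability DataFrame).
    """
    Xs = _log_standardize(expr)
    present = [g for g in classifier.genes if g in Xs.index]
    if len(present) < 0.5 * len(classifier.genes):
        raise ValueError(
            f"only {len(present)}/{len(classifier.genes)} classifier genes present"
        )
    missing = [g for g in classifier.genes if g not in Xs.index]
    if missing:
        logger.info("imputing %d absent classifier genes as 0", len(missing))
    mat = pd.DataFrame(0.0, index=classifier.genes, columns=Xs.columns)
    mat.loc[present] = Xs.loc[present]
    scores = classifier.coefficients @ mat.to_numpy() + classifier.intercepts[:, None]
    scores -= scores.max(axis=0, keepdims=True)
    probs = np.exp(scores)
    probs /= probs.sum(axis=0, keepdims=True)
    labels = np.array([classifier.classes[i] for i in probs.argmax(axis=0)])
    prob_df = pd.DataFrame(probs.T, index=Xs.columns,
                           columns=[str(c) for c in classifier.classes])
    return labels, prob_df


def _precision_recall(pred, truth, classes) -> pd.DataFrame:
    rows = []
    for c in classes:
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append((c, precision, recall, tp + fn))
    return pd.DataFrame(rows, columns=["class", "precision", "recall", "support"]
                        ).set_index("class")


def evaluate(pred, truth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class precision/recall plus the confusion matrix."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    classes = np.unique(np.concatenate([truth, pred]))
    metrics = _precision_recall(pred, truth, classes)
    cm = pd.DataFrame(
        confusion_matrix(truth, pred, labels=classes),
        index=[f"true_{c}" for c in classes],
        columns=[f"pred_{c}" for c in classes],
    )
    return metrics, cm
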