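"""Outcome analysis: Kaplan-Meier curves, global log-rank, Cox PH.

The estimators are implemented directly from their defining risk-set
computations: the product-limit estimator, the K-group log-rank
statistic with hypergeometric variance, and Newton-Raphson maximization
of the Breslow partial likelihood.  Breslow tie handling is used
throughout; with continuous simulated event times ties are rare and the
choice is immaterial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class KmCurve:
    """Product-limit survival curve.

    ``median`` follows the convention: smallest event time t with
    S(t) <= 0.5, NaN if the curve never reaches 0.5.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float


def km_estimate(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimate over the distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty input")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    event_times = np.unique(time[event == 1])
    surv = []
    at_risk = []
    n_events = []
    s = 1.0
    for t in event_times:
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        n_events.append(d)
    surv_arr = np.array(surv)
    below = np.nonzero(surv_arr <= 0.5)[0] if surv_arr.size else np.array([])
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KmCurve(
        times=event_times,
        survival=surv_arr,
        at_risk=np.array(at_risk),
        n_events=np.array(n_events),
        median=median,
    )


def logrank_global(labels, time, event) -> tuple[float, int, float]:
    """K-group log-rank test: (chi2, df, p).

    At every distinct event time the observed events per group are
    compared with their hypergeometric expectation given the risk sets;
    the quadratic form uses the K-1 leading groups.
    """
    labels = np.asarray(labels)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    event_times = np.unique(time[event == 1])
    obs = np.zeros(k)
    exp = np.zeros(k)
    var = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        n_g = np.array([(at_risk & (labels == g)).sum() for g in groups], float)
        d_g = np.array(
            [((time == t) & (event == 1) & (labels == g)).sum() for g in groups], float
        )
        obs += d_g
        exp += d * n_g / n
        if n > 1:
            frac = n_g / n
            scale = d * (n - d) / (n - 1)
            var += scale * (np.diag(frac) - np.outer(frac, frac))
    z = (obs - exp)[: k - 1]
    v = var[: k - 1, : k - 1]
    try:
        chi2 = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(v) @ z)
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def cox_ph(
    covariates: pd.DataFrame,
    time,
    event,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Cox proportional hazards via Newton-Raphson on the Breslow
    partial likelihood.

    Returns a per-covariate table with ``coef``, ``hr`` (exp(coef)),
    ``se`` and two-sided Wald ``p``.  A ``converged`` attribute is set
    on the result; separation or non-convergence warns rather than
    raising, with the diagnostics left in the table.
    """
    X = covariates.to_numpy(float)
    names = list(covariates.columns)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n, p = X.shape
    const = [names[j] for j in range(p) if np.ptp(X[:, j]) == 0]
    if const:
        raise ValueError(f"constant covariates: {const}")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events observed")
    if n_events < p:
        raise ValueError(f"{n_events} events < {p} covariates")
    # center covariates for numerical stability (coefs are unaffected)
    Xc = X - X.mean(axis=0)
    order = np.argsort(-time)  # decreasing time: risk sets grow as we scan
    Xo, to, eo = Xc[order], time[order], event[order]

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = Xo @ beta
        w = np.exp(eta)
        # cumulative sums over the growing risk set
        s0 = np.cumsum(w)
        s1 = np.cumsum(w[:, None] * Xo, axis=0)
        s2 = np.cumsum(w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
        # Breslow: all subjects with time >= t_i are at risk; with the
        # decreasing sort, ties share the full cumulative sum at the last
        # tied index
        last_idx = np.searchsorted(-to, -to, side="right") - 1
        ev = eo == 1
        li = last_idx[ev]
        grad = Xo[ev].sum(axis=0) - (s1[li] / s0[li, None]).sum(axis=0)
        mean_x = s1[li] / s0[li, None]
        info = np.zeros((p, p))
        info += (s2[li] / s0[li, None, None]).sum(axis=0)
        info -= np.einsum("ij,ik->jk", mean_x, mean_x)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; possible separation")
            break
        # step-halving to keep the partial likelihood increasing
        ll_old = _breslow_loglik(beta, Xo, to, eo)
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            if _breslow_loglik(cand, Xo, to, eo) >= ll_old - 1e-12:
                break
            factor /= 2.0
        beta_new = beta + factor * step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged:
        warnings.warn("Cox Newton-Raphson did not converge")
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame(
        {"coef": beta, "hr": np.exp(beta), "se": se, "p": pvals}, index=names
    )
    out.attrs["converged"] = converged
    return out


def _breslow_loglik(beta, Xo, to, eo) -> float:
    eta = Xo @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    last_idx = np.searchsorted(-to, -to, side="right") - 1
    ev = eo == 1
    return float(eta[ev].sum() - np.log(s0[last_idx[ev]]).sum())
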