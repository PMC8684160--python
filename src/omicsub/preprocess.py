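"""Normalization, feature filtering and genomic-burden statistics.

The preprocessing recipe mirrors common practice for bulk tumor
multi-omics: expression is scaled per sample against the geometric mean
of three stable housekeeping genes, genes are ranked by coefficient of
variation for downstream feature selection, missense mutations are kept
only above a cohort prevalence threshold, and copy-number segments are
summarized both as a per-sample genomic-loss fraction and as a
cytoband-level copy-state matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .dataio import CnvSegmentProfile

logger = logging.getLogger(__name__)

# Candidate housekeeping genes screened for stability; the three with
# the lowest across-sample SD of log2(TPM+1) become the normalizers.
DEFAULT_HOUSEKEEPING_CANDIDATES = (
    "ACTB", "GAPDH", "B2M", "HPRT1", "RPL13A", "SDHA",
    "TBP", "UBC", "NONO", "PGK1", "VPS29",
)


def select_housekeeping(
    expr: pd.DataFrame,
    candidates=DEFAULT_HOUSEKEEPING_CANDIDATES,
    n_select: int = 3,
) -> list[str]:
    """Pick the ``n_select`` candidates with smallest SD of log2(TPM+1).

    Ties at the cutoff resolve by lexicographic gene id so the choice is
    deterministic.
    """
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise KeyError(f"housekeeping candidates absent from matrix: {missing}")
    logged = np.log2(expr.loc[list(candidates)] + 1.0)
    sds = logged.std(axis=1, ddof=1)
    order = sorted(candidates, key=lambda g: (sds[g], g))
    return order[:n_select]


def normalize_housekeeping(expr: pd.DataFrame, hk_genes) -> pd.DataFrame:
    """Scale each sample by the geometric mean of its housekeeping TPMs.

    Housekeeping rows are retained (their per-sample geometric mean
    becomes exactly 1).  A non-positive housekeeping value is an error:
    silently adding a pseudocount would distort the scaling factor.
    """
    hk_genes = list(hk_genes)
    missing = [g for g in hk_genes if g not in expr.index]
    if missing:
        raise KeyError(f"housekeeping genes absent from matrix: {missing}")
    hk = expr.loc[hk_genes]
    bad = hk.columns[(hk <= 0).any(axis=0)]
    if len(bad):
        raise ValueError(
            f"non-positive housekeeping expression in samples: {list(bad[:5])}"
        )
    geo_mean = np.exp(np.log(hk).mean(axis=0))
    return expr.div(geo_mean, axis=1)


def select_high_variance(expr: pd.DataFrame, n_top: int) -> list[str]:
    """Rank genes by coefficient of variation (SD/mean on the TPM scale).

    Genes with zero mean are excluded before ranking (their CV is
    undefined) and logged.  Returns the top ``n_top`` gene ids in
    descending CV order; ties resolve by gene id.
    """
    if n_top > expr.shape[0]:
        raise ValueError(f"n_top={n_top} exceeds {expr.shape[0]} genes")
    means = expr.mean(axis=1)
    zero_mean = means.index[means == 0]
    if len(zero_mean):
        logger.info("excluding %d zero-mean genes from CV ranking", len(zero_mean))
    kept = expr.drop(index=zero_mean)
    cv = kept.std(axis=1, ddof=1) / kept.mean(axis=1)
    order = sorted(cv.index, key=lambda g: (-cv[g], g))
    return order[:n_top]


def filter_snv(mut: pd.DataFrame, threshold: float = 0.03) -> pd.DataFrame:
    """Keep genes mutated in at least ``threshold`` of samples (inclusive)."""
    if not mut.isin([0, 1]).all().all():
        raise ValueError("mutation matrix must be binary")
    prevalence = mut.mean(axis=1)
    kept = mut.loc[prevalence >= threshold]
    if kept.empty:
        warnings.warn("no mutated gene reaches the prevalence threshold")
    return kept


def _union_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open integer intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_start, cur_end = intervals[0]
    for start, end in intervals[1:]:
        if start > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    return total + (cur_end - cur_start)


def genomic_loss_fraction(profile: CnvSegmentProfile) -> float:
    """Fraction of the genome covered by loss-called segments.

    Overlapping loss segments are unioned before summing so the value is
    bounded in [0, 1]; both homozygous and heterozygous deletions carry
    the same ``loss`` call and count equally.
    """
    if profile.genome_size <= 0:
        raise ValueError("genome_size must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, call in profile.segments:
        if call == "loss":
            by_chrom.setdefault(chrom, []).append((start, end))
    loss_bp = sum(_union_length(iv) for iv in by_chrom.values())
    return loss_bp / profile.genome_size


def aggregate_cnv_to_cytobands(
    profiles: dict[str, CnvSegmentProfile],
    cytoband_map: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Collapse segment calls to an integer copy state per cytoband.

    The state of a band is the call covering the majority of its bases
    (uncovered bases count as neutral): loss -> 1, neutral -> 2,
    gain -> 3.  Exact ties resolve toward the lower copy state.  Returns
    ``(states, loss_indicator, gain_indicator)``, each cytobands x
    samples.
    """
    bands = cytoband_map.reset_index(drop=True)
    samples = list(profiles)
    states = np.full((len(bands), len(samples)), 2, dtype=int)
    uncovered = 0
    band_arrays = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in bands.groupby("chrom")
    }
    band_rows = {
        chrom: grp.index.to_numpy() for chrom, grp in bands.groupby("chrom")
    }
    for j, sid in enumerate(samples):
        cover: dict[int, dict[str, int]] = {}
        touching: dict[int, list[tuple[int, int]]] = {}
        for chrom, seg_start, seg_end, call in profiles[sid].segments:
            if chrom not in band_arrays:
                continue
            arr = band_arrays[chrom]
            rows = band_rows[chrom]
            overlap = np.minimum(arr[:, 1], seg_end) - np.maximum(arr[:, 0], seg_start)
            for k in np.nonzero(overlap > 0)[0]:
                d = cover.setdefault(rows[k], {"loss": 0, "neutral": 0, "gain": 0})
                d[call] += int(overlap[k])
                touching.setdefault(rows[k], []).append(
                    (max(int(arr[k, 0]), seg_start), min(int(arr[k, 1]), seg_end))
                )
        for i in range(len(bands)):
            length = int(bands.loc[i, "end"] - bands.loc[i, "start"])
            d = cover.get(i)
            if d is None:
                uncovered += 1
                continue
            counts = dict(d)
            # bases not covered by any segment count as neutral; overlapping
            # segments each contribute their own call, mirroring a per-base
            # tally
            counts["neutral"] += length - _union_length(touching[i])
            # majority call; ties resolve toward the lower copy state
            best = max(counts, key=lambda c: (counts[c], -("loss", "neutral", "gain").index(c)))
            states[i, j] = {"loss": 1, "neutral": 2, "gain": 3}[best]
    if uncovered:
        logger.info("%d band/sample pairs had no covering segment (neutral)", uncovered)
    idx = bands["band"]
    state_df = pd.DataFrame(states, index=idx, columns=samples)
    loss_ind = (state_df < 2).astype(int)
    gain_ind = (state_df > 2).astype(int)
    return state_df, loss_ind, gain_ind


def standardize_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene to median 0 and SD 1 across samples.

    Zero-SD genes cannot be scaled and are dropped with a log message.
    """
    if expr.shape[1] < 2:
        raise ValueError("standardization needs at least 2 samples")
    sds = expr.std(axis=1, ddof=1)
    constant = sds.index[sds == 0]
    if len(constant):
        logger.info("dropping %d constant genes before standardization", len(constant))
    kept = expr.drop(index=constant)
    med = kept.median(axis=1)
    return kept.sub(med, axis=0).div(sds.drop(index=constant), axis=0)
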