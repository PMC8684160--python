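"""End-to-end orchestration: simulate -> preprocess -> cluster ->
characterize -> survival -> classify -> regulators.

One configuration object drives all stages; every stage's outputs are
written as plain-text tables under the run directory, checksummed into
a reproducibility manifest, and summarized in a markdown report.  With
identical configuration and seed the manifest checksums are identical
across runs (timestamps and wall-clock excluded from the comparison).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import characterize, classify, integrate, preprocess, regulators, survival
from .dataio import write_clinical, write_matrix, write_regulons, write_seg
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_dataset,
    simulate_regulons,
    simulate_survival,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Desk-scale defaults so a full run finishes in minutes."""

    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_samples=120, n_genes=150, n_subgroups=3,
        signature_genes_per_subgroup=15, loss_subgroup_id=2, seed=0,
    ))
    k_min: int = 2
    k_max: int = 5
    n_consensus_iter: int = 8
    high_risk_top_fraction: float = 0.15
    seed: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "seed": config.seed,
        "stages": {},
    }
    report: list[str] = ["# Integrative subtyping run report", ""]
    stage_outputs: dict[str, list[Path]] = {}

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][name] = {
            "wall_clock_s": round(time.perf_counter() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }
        stage_outputs[name] = files

    try:
        # --- simulate ----------------------------------------------------
        t0 = time.perf_counter()
        sim = config.simulation
        dataset, truth = simulate_dataset(sim)
        surv_table = simulate_survival(truth, sim)
        regulon_set = simulate_regulons(sim, truth)
        files = [out / "expression.tsv", out / "cnv_segments.seg",
                 out / "mutations.tsv", out / "sv_flags.tsv",
                 out / "clinical.tsv", out / "regulons.tsv"]
        write_matrix(dataset.expression, files[0])
        write_seg(dataset.cnv_profiles.values(), files[1])
        write_matrix(dataset.mutations, files[2])
        write_matrix(dataset.sv_flags, files[3])
        write_clinical(surv_table, files[4])
        write_regulons(regulon_set, files[5])
        finish_stage("simulate", t0, files)

        # --- preprocess ---------------------------------------------------
        t0 = time.perf_counter()
        hk = preprocess.select_housekeeping(dataset.expression)
        expr_norm = preprocess.normalize_housekeeping(dataset.expression, hk)
        loss = pd.Series(
            {s: preprocess.genomic_loss_fraction(p)
             for s, p in dataset.cnv_profiles.items()},
            name="loss_fraction",
        )
        mut_kept = preprocess.filter_snv(dataset.mutations)
        f = out / "loss_fraction.tsv"
        loss.to_frame().to_csv(f, sep="\t", index_label="sample")
        finish_stage("preprocess", t0, [f])

        # --- cluster ------------------------------------------------------
        t0 = time.perf_counter()
        dataset_norm = dataset
        dataset_norm.expression = expr_norm
        res = integrate.consensus_select_k(
            dataset_norm, k_range=range(config.k_min, config.k_max + 1),
            n_iter=config.n_consensus_iter, seed=config.seed,
        )
        labels = res.labels
        f_labels = out / "cluster_labels.tsv"
        pd.Series(labels, index=dataset.sample_ids, name="cluster"
                  ).to_frame().to_csv(f_labels, sep="\t", index_label="sample")
        f_cons = out / "consensus_matrix.tsv"
        pd.DataFrame(np.nan_to_num(res.consensus, nan=0.5),
                     index=dataset.sample_ids, columns=dataset.sample_ids
                     ).to_csv(f_cons, sep="\t", float_format="%.4g")
        f_kfreq = out / "k_frequency.tsv"
        pd.Series(res.k_frequency, name="count").sort_index().to_frame().to_csv(
            f_kfreq, sep="\t", index_label="K")
        finish_stage("cluster", t0, [f_labels, f_cons, f_kfreq])
        sizes = pd.Series(labels).value_counts().sort_index()
        report += [f"Chosen K: **{res.chosen_K}** "
                   f"(membership consistency {res.membership_consistency:.3f})",
                   "", "Cluster sizes: " +
                   ", ".join(f"{k}: {v}" for k, v in sizes.items()), ""]

        # --- characterize -------------------------------------------------
        t0 = time.perf_counter()
        binary_feats = pd.concat([
            mut_kept, dataset.sv_flags,
            (dataset.cnv_states < 2).astype(int).rename(
                index=lambda b: f"loss_{b}"),
        ])
        enr = characterize.enrich_binary(labels, binary_feats)
        f_enr = out / "binary_enrichment.tsv"
        enr.to_csv(f_enr, sep="\t", index=False, float_format="%.4g")
        # per-cluster loss burden
        loss_by_cluster = loss.groupby(labels).median()
        f_loss = out / "loss_by_cluster.tsv"
        loss_by_cluster.to_frame().to_csv(f_loss, sep="\t", index_label="cluster")
        finish_stage("characterize", t0, [f_enr, f_loss])
        report += ["Median genomic-loss fraction by cluster: " +
                   ", ".join(f"{k}: {v:.3f}"
                             for k, v in loss_by_cluster.items()), ""]

        # --- survival -----------------------------------------------------
        t0 = time.perf_counter()
        chi2, df_, p = survival.logrank_global(labels, surv_table.time,
                                               surv_table.event)
        km_rows = []
        for c in np.unique(labels):
            curve = survival.km_estimate(surv_table.time[labels == c],
                                         surv_table.event[labels == c])
            km_rows.append((c, int((labels == c).sum()), curve.median))
        km_df = pd.DataFrame(km_rows, columns=["cluster", "n", "median_months"])
        f_km = out / "km_by_cluster.tsv"
        km_df.to_csv(f_km, sep="\t", index=False, float_format="%.4g")
        _plot_km(labels, surv_table, out / "km_curves.png")
        hr_cluster = int(loss_by_cluster.idxmax())
        covs = pd.DataFrame({
            "high_risk_cluster": (labels == hr_cluster).astype(float),
            "iss_3": (surv_table.data["iss_stage"] == 3).astype(float).to_numpy(),
        })
        cox = survival.cox_ph(covs, surv_table.time, surv_table.event)
        f_cox = out / "cox_coefficients.tsv"
        cox.to_csv(f_cox, sep="\t", index_label="covariate", float_format="%.4g")
        finish_stage("survival", t0, [f_km, f_cox])
        report += [f"Global log-rank: chi2={chi2:.2f}, df={df_}, p={p:.3g}",
                   "", cox.to_markdown(), ""]

        # --- classify -----------------------------------------------------
        t0 = time.perf_counter()
        clf = classify.train_classifier(
            dataset.expression, labels,
            n_candidate_genes=min(200, dataset.expression.shape[0]),
            cv_replicates=3, n_folds=5, seed=config.seed,
        )
        f_model = out / "classifier_coefficients.tsv"
        clf.to_frame().to_csv(f_model, sep="\t", index_label="gene",
                              float_format="%.6g")
        f_metrics = out / "classifier_metrics.tsv"
        clf.cv_metrics.to_csv(f_metrics, sep="\t", float_format="%.4g")
        finish_stage("classify", t0, [f_model, f_metrics])
        report += ["Classifier held-out metrics:", "", clf.cv_metrics.to_markdown(), ""]

        # --- regulators ---------------------------------------------------
        t0 = time.perf_counter()
        sig = regulators.make_signature(np.log2(dataset.expression + 1.0),
                                        labels, hr_cluster)
        mr = regulators.msviper(sig, regulon_set, n_null=200, seed=config.seed)
        f_mr = out / "master_regulators.tsv"
        mr.to_csv(f_mr, sep="\t", index_label="regulator", float_format="%.4g")
        finish_stage("regulators", t0, [f_mr])
        report += [f"Top regulators for cluster {hr_cluster}:", "",
                   mr.head(5).to_markdown(), ""]
    except Exception as exc:
        manifest["failed_stage"] = _next_stage_name(manifest)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise RuntimeError(
            f"pipeline aborted in stage {manifest['failed_stage']!r}: {exc}"
        ) from exc

    (out / "report.md").write_text("\n".join(report))
    manifest["report"] = "report.md"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _plot_km(labels, surv_table, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in np.unique(labels):
        curve = survival.km_estimate(surv_table.time[labels == c],
                                     surv_table.event[labels == c])
        ax.step(np.concatenate([[0], curve.times]),
                np.concatenate([[1.0], curve.survival]),
                where="post", label=f"cluster {c}")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


_STAGE_ORDER = ["simulate", "preprocess", "cluster", "characterize",
                "survival", "classify", "regulators"]


def _next_stage_name(manifest: dict) -> str:
    done = set(manifest["stages"])
    for s in _STAGE_ORDER:
        if s not in done:
            return s
    return "report"


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    sim = d["simulation"]
    for key, val in list(sim.items()):
        if isinstance(val, np.ndarray):
            sim[key] = val.tolist()
        elif isinstance(val, pd.DataFrame):
            sim[key] = "<table>"
        elif isinstance(val, list) and val and isinstance(val[0], tuple):
            sim[key] = [list(t) for t in val]
    # cytobands table hashes instead of inlining
    if isinstance(config.simulation.cytobands, pd.DataFrame):
        sim["cytobands"] = hashlib.sha256(
            config.simulation.cytobands.to_csv().encode()).hexdigest()
    return d
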