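"""Synthetic multi-omics cohort generator with planted subgroup structure.

The generator emulates a newly diagnosed multiple myeloma cohort as it
arrives at the subtyping pipeline: a TPM-like expression matrix with
per-subgroup signature genes and stable housekeeping genes, per-sample
copy-number segment calls (one designated subgroup carries a broad
genomic loss of ~9.5% of the genome versus ~3% elsewhere), binary
missense mutations with subgroup-enriched genes, IgH-translocation /
hyperdiploidy flags, and subgroup-dependent survival.  Ground truth
(labels, planted signatures, loss fractions, active regulators) is
returned alongside so every downstream stage can be scored against the
construction.

Each omics layer draws from its own RNG stream spawned from the master
seed, so adding or resizing one layer never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (
    SV_FLAGS,
    CnvSegmentProfile,
    MultiOmicsDataset,
    Regulon,
    RegulonSet,
    SurvivalTable,
)
from .preprocess import DEFAULT_HOUSEKEEPING_CANDIDATES, aggregate_cnv_to_cytobands

_STREAMS = (
    "proportions", "labels", "genes", "expression", "cnv",
    "mutations", "sv", "survival", "regulons",
)


def make_default_genome(
    n_chromosomes: int = 22,
    chrom_length: int = 10_000_000,
    bands_per_chromosome: int = 8,
) -> tuple[list[tuple[str, int]], pd.DataFrame]:
    """Desk-scale synthetic genome: 22 x 10 Mb with 8 cytobands each."""
    chroms = [(f"chr{i}", chrom_length) for i in range(1, n_chromosomes + 1)]
    rows = []
    for chrom, length in chroms:
        band_len = length // bands_per_chromosome
        for b in range(bands_per_chromosome):
            start = b * band_len
            end = length if b == bands_per_chromosome - 1 else start + band_len
            rows.append((chrom, start, end, f"{chrom}_b{b + 1}"))
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "band"])
    return chroms, bands


@dataclass
class SimulationConfig:
    """Cohort-level parameters of the generator.

    Defaults emulate the discovery-cohort geometry: 500 samples in 12
    subgroups of 5-12% each, one subgroup (index 7) with broad genomic
    loss centered at 9.5% of the genome versus 3% elsewhere, and an
    elevated hazard (HR 2.5) for that subgroup.
    """

    n_samples: int = 500
    n_genes: int = 1000
    n_subgroups: int = 12
    subgroup_proportions: np.ndarray | None = None  # default: jittered uniform
    signature_genes_per_subgroup: int = 25
    signature_effect: float = 1.5       # log2 shift of signature genes
    signature_up_fraction: float = 0.7  # fraction of signature genes shifted up
    noise_sd: float = 0.6               # log2-scale Gaussian noise
    hk_noise_factor: float = 0.1        # housekeeping noise = factor * noise_sd
    genome: list[tuple[str, int]] | None = None
    cytobands: pd.DataFrame | None = None
    loss_subgroup_id: int = 7
    loss_frac_mean_broad: float = 0.095
    loss_frac_mean_other: float = 0.03
    loss_frac_concentration: float = 150.0
    focal_gain_bands_per_subgroup: int = 3
    focal_gain_rate: float = 0.6
    cnv_dosage_effect: float = 0.4      # log2 shift per lost/gained copy
    n_mutation_genes: int = 40
    mutation_background_rate: float = 0.02
    mutation_enriched_rate: float = 0.25
    mutation_enriched_per_subgroup: int = 2
    sv_rates: pd.DataFrame | None = None  # flags x subgroups probabilities
    hazard_ratios: np.ndarray | None = None  # default: 2.5 for loss subgroup
    baseline_median_months: float = 60.0
    censoring_rate: float = 0.3
    regulon_size: int = 40
    n_decoy_regulons: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 2:
            raise ValueError("n_subgroups must be >= 2")
        if self.genome is None or self.cytobands is None:
            self.genome, self.cytobands = make_default_genome()
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        n_hk = len(DEFAULT_HOUSEKEEPING_CANDIDATES)
        needed = n_hk + self.signature_genes_per_subgroup * self.n_subgroups
        if needed > self.n_genes:
            raise ValueError(
                f"{self.n_subgroups} subgroups x {self.signature_genes_per_subgroup} "
                f"signature genes plus {n_hk} housekeeping genes exceed n_genes={self.n_genes}"
            )
        if self.subgroup_proportions is not None:
            p = np.asarray(self.subgroup_proportions, float)
            if len(p) != self.n_subgroups:
                raise ValueError("subgroup_proportions length mismatch")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("subgroup_proportions must sum to 1")
            self.subgroup_proportions = p
        for name in ("loss_frac_mean_broad", "loss_frac_mean_other",
                     "censoring_rate", "focal_gain_rate",
                     "mutation_background_rate", "mutation_enriched_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.loss_subgroup_id < self.n_subgroups:
            raise ValueError("loss_subgroup_id out of range")
        if self.hazard_ratios is not None:
            hr = np.asarray(self.hazard_ratios, float)
            if (hr <= 0).any():
                raise ValueError("hazard ratios must be positive")
            self.hazard_ratios = hr

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.genome)

    def default_hazard_ratios(self) -> np.ndarray:
        hr = np.ones(self.n_subgroups)
        hr[self.loss_subgroup_id] = 2.5
        return hr

    def default_sv_rates(self) -> pd.DataFrame:
        """Flag x subgroup Bernoulli rates loosely mirroring MM biology:
        hyperdiploidy dominates the first half of the subgroups, IgH
        translocations the rest, with t(4;14)/t(14;16) enriched in the
        broad-loss subgroup."""
        K = self.n_subgroups
        rates = pd.DataFrame(0.02, index=list(SV_FLAGS), columns=range(K))
        n_hy = K // 2
        rates.loc["HY", range(n_hy)] = 0.85
        non_hy = [k for k in range(n_hy, K)]
        for i, k in enumerate(non_hy):
            flag = SV_FLAGS[i % 3]
            rates.loc[flag, k] = 0.5
        rates.loc["t(4;14)", self.loss_subgroup_id] = 0.45
        rates.loc["t(14;16)", self.loss_subgroup_id] = 0.25
        return rates


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    labels: np.ndarray
    planted_signature_genes: dict[int, list[str]]
    signature_signs: dict[int, dict[str, int]]
    planted_loss_fractions: np.ndarray
    planted_regulators: dict[int, str]
    gene_positions: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.size and labels.min() < 0:
            raise ValueError("labels out of range")
        k = len(self.planted_signature_genes)
        if k and labels.size and labels.max() >= k:
            raise ValueError("labels out of range")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _draw_proportions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.subgroup_proportions is not None:
        return config.subgroup_proportions
    # jittered uniform: each subgroup lands within roughly 5-12% for K=12
    raw = 1.0 + rng.uniform(-0.3, 0.3, size=config.n_subgroups)
    return raw / raw.sum()


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def _place_loss_segments(
    target_fraction: float,
    bands: pd.DataFrame,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    """Sample cytobands without replacement until the unioned loss length
    reaches the target; the final band is truncated to hit it exactly."""
    if target_fraction <= 0:
        return []
    genome_size = int((bands["end"] - bands["start"]).sum())
    target_bp = int(round(target_fraction * genome_size))
    order = rng.permutation(len(bands))
    segments: list[tuple[str, int, int]] = []
    acc = 0
    for idx in order:
        if acc >= target_bp:
            break
        chrom = bands.iloc[idx]["chrom"]
        start = int(bands.iloc[idx]["start"])
        end = int(bands.iloc[idx]["end"])
        length = min(end - start, target_bp - acc)
        segments.append((chrom, start, start + length))
        acc += length
    return segments


def simulate_dataset(config: SimulationConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate all omics layers plus ground truth.

    Expression is built on the log2 scale as baseline + subgroup
    signature shifts + copy-number dosage (genes inside a lost/gained
    region shift down/up by ``cnv_dosage_effect``) + Gaussian noise,
    then exponentiated to a TPM-like positive scale.  Identical
    (config, seed) reproduce bitwise-identical outputs.
    """
    rngs = _streams(config.seed)
    K = config.n_subgroups
    bands = config.cytobands

    # --- sample labels -----------------------------------------------------
    proportions = _draw_proportions(config, rngs["proportions"])
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    labels = rngs["labels"].choice(K, size=config.n_samples, p=proportions)

    # --- gene registry and genomic positions -------------------------------
    hk_genes = list(DEFAULT_HOUSEKEEPING_CANDIDATES)
    n_other = config.n_genes - len(hk_genes)
    gene_ids = hk_genes + [f"G{i + 1:05d}" for i in range(n_other)]
    rng_genes = rngs["genes"]
    chrom_names = [c for c, _ in config.genome]
    chrom_lengths = {c: l for c, l in config.genome}
    gene_chrom = rng_genes.choice(chrom_names, size=config.n_genes)
    gene_pos = np.array(
        [rng_genes.integers(0, chrom_lengths[c]) for c in gene_chrom]
    )
    positions = pd.DataFrame(
        {"chrom": gene_chrom, "pos": gene_pos}, index=gene_ids
    )

    # --- planted signatures ------------------------------------------------
    sig_genes: dict[int, list[str]] = {}
    signs: dict[int, dict[str, int]] = {}
    cursor = len(hk_genes)
    n_up = int(np.ceil(config.signature_up_fraction * config.signature_genes_per_subgroup))
    for k in range(K):
        block = gene_ids[cursor: cursor + config.signature_genes_per_subgroup]
        cursor += config.signature_genes_per_subgroup
        sig_genes[k] = list(block)
        signs[k] = {g: (1 if i < n_up else -1) for i, g in enumerate(block)}

    # --- CNV layer ---------------------------------------------------------
    rng_cnv = rngs["cnv"]
    a_b, b_b = _beta_params(config.loss_frac_mean_broad, config.loss_frac_concentration)
    a_o, b_o = _beta_params(config.loss_frac_mean_other, config.loss_frac_concentration)
    loss_fracs = np.where(
        labels == config.loss_subgroup_id,
        rng_cnv.beta(a_b, b_b, size=config.n_samples),
        rng_cnv.beta(a_o, b_o, size=config.n_samples),
    )
    # subgroup-characteristic focal gain bands
    gain_band_idx = {
        k: rng_cnv.choice(len(bands), size=config.focal_gain_bands_per_subgroup,
                          replace=False)
        for k in range(K)
    }
    profiles: dict[str, CnvSegmentProfile] = {}
    genome_size = config.genome_size
    for i, sid in enumerate(sample_ids):
        loss_iv = _place_loss_segments(loss_fracs[i], bands, rng_cnv)
        segments = [(c, s, e, "loss") for c, s, e in loss_iv]
        lost_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in loss_iv:
            lost_by_chrom.setdefault(c, []).append((s, e))
        for idx in gain_band_idx[labels[i]]:
            if rng_cnv.random() >= config.focal_gain_rate:
                continue
            chrom = bands.iloc[idx]["chrom"]
            start = int(bands.iloc[idx]["start"])
            end = int(bands.iloc[idx]["end"])
            overlaps = any(
                s < end and start < e for s, e in lost_by_chrom.get(chrom, [])
            )
            if not overlaps:
                segments.append((chrom, start, end, "gain"))
        profiles[sid] = CnvSegmentProfile(
            sample_id=sid, segments=segments, genome_size=genome_size
        )

    # --- expression layer --------------------------------------------------
    rng_expr = rngs["expression"]
    base_log2 = rng_expr.uniform(2.0, 8.0, size=config.n_genes)
    base_log2[: len(hk_genes)] = 6.0
    log2_expr = np.tile(base_log2[:, None], (1, config.n_samples))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for k in range(K):
        members = np.nonzero(labels == k)[0]
        if len(members) == 0:
            continue
        for g in sig_genes[k]:
            log2_expr[gene_index[g], members] += signs[k][g] * config.signature_effect
    # copy-number dosage on genes inside lost/gained regions
    if config.cnv_dosage_effect != 0:
        pos_by_chrom = {
            c: (np.nonzero((positions["chrom"] == c).to_numpy())[0],
                positions.loc[positions["chrom"] == c, "pos"].to_numpy())
            for c in chrom_names
        }
        for j, sid in enumerate(sample_ids):
            for chrom, s, e, call in profiles[sid].segments:
                rows, pos = pos_by_chrom[chrom]
                hit = rows[(pos >= s) & (pos < e)]
                shift = -config.cnv_dosage_effect if call == "loss" else config.cnv_dosage_effect
                log2_expr[hit, j] += shift
    gene_sd = np.full(config.n_genes, config.noise_sd)
    gene_sd[: len(hk_genes)] = config.noise_sd * config.hk_noise_factor
    log2_expr += rng_expr.standard_normal(log2_expr.shape) * gene_sd[:, None]
    expression = pd.DataFrame(
        np.exp2(log2_expr), index=gene_ids, columns=sample_ids
    )

    # --- mutation layer ----------------------------------------------------
    rng_mut = rngs["mutations"]
    non_sig = gene_ids[cursor:]
    if len(non_sig) >= config.n_mutation_genes:
        mut_genes = list(rng_mut.choice(non_sig, size=config.n_mutation_genes,
                                        replace=False))
    else:
        mut_genes = list(rng_mut.choice(gene_ids[len(hk_genes):],
                                        size=config.n_mutation_genes, replace=False))
    rates = np.full((config.n_mutation_genes, K), config.mutation_background_rate)
    for k in range(K):
        enriched = rng_mut.choice(config.n_mutation_genes,
                                  size=config.mutation_enriched_per_subgroup,
                                  replace=False)
        rates[enriched, k] = config.mutation_enriched_rate
    mut = (rng_mut.random((config.n_mutation_genes, config.n_samples))
           < rates[:, labels]).astype(int)
    mutations = pd.DataFrame(mut, index=mut_genes, columns=sample_ids)

    # --- SV layer ----------------------------------------------------------
    rng_sv = rngs["sv"]
    sv_rates = config.sv_rates if config.sv_rates is not None else config.default_sv_rates()
    sv = (rng_sv.random((len(sv_rates), config.n_samples))
          < sv_rates.to_numpy()[:, labels]).astype(int)
    sv_flags = pd.DataFrame(sv, index=list(sv_rates.index), columns=sample_ids)

    # --- cytoband copy-state matrix ----------------------------------------
    cnv_states, _, _ = aggregate_cnv_to_cytobands(profiles, bands)

    dataset = MultiOmicsDataset(
        expression=expression,
        cnv_states=cnv_states,
        mutations=mutations,
        sv_flags=sv_flags,
    )
    dataset.cnv_profiles = profiles  # segment-level calls travel with the dataset
    truth = GroundTruth(
        labels=labels,
        planted_signature_genes=sig_genes,
        signature_signs=signs,
        planted_loss_fractions=loss_fracs,
        planted_regulators={k: f"MR_{k}" for k in range(K)},
        gene_positions=positions,
    )
    return dataset, truth


def simulate_survival(truth: GroundTruth, config: SimulationConfig) -> SurvivalTable:
    """Exponential event times with per-subgroup hazard ratios.

    Each subgroup's hazard is ``baseline * HR[k]`` where the baseline
    rate gives the configured median survival.  Censoring is
    independent: a ``censoring_rate`` coin flips a sample to censored at
    a uniform fraction of its latent event time.
    """
    rng = _streams(config.seed)["survival"]
    labels = np.asarray(truth.labels)
    hr = (config.hazard_ratios if config.hazard_ratios is not None
          else config.default_hazard_ratios())
    if (np.asarray(hr) <= 0).any():
        raise ValueError("hazard ratios must be positive")
    base_rate = np.log(2.0) / config.baseline_median_months
    rate = base_rate * np.asarray(hr)[labels]
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(len(labels)) < config.censoring_rate
    u = rng.random(len(labels))
    time = np.where(censored, np.maximum(t_event * u, 1e-6), t_event)
    event = (~censored).astype(int)
    # ISS stage loosely associated with the high-risk subgroup
    p_iss3 = np.where(labels == config.loss_subgroup_id, 0.5, 0.25)
    iss = 1 + (rng.random(len(labels)) < 0.55).astype(int)
    iss = np.where(rng.random(len(labels)) < p_iss3, 3, iss)
    sample_ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    df = pd.DataFrame(
        {"time": time, "event": event, "iss_stage": iss, "subgroup": labels},
        index=pd.Index(sample_ids, name="sample"),
    )
    return SurvivalTable(df)


def simulate_regulons(config: SimulationConfig, truth: GroundTruth) -> RegulonSet:
    """Regulons with known activity plus uninformative decoys.

    For each planted regulator, positive-mode targets are drawn from
    genes up-shifted in its subgroup and negative-mode targets from
    down-shifted genes; decoy regulons draw targets uniformly from the
    gene universe with random modes.
    """
    if config.regulon_size > config.n_genes:
        raise ValueError("regulon_size exceeds gene universe")
    rng = _streams(config.seed)["regulons"]
    all_genes = list(truth.gene_positions.index)
    out = RegulonSet()
    for k, reg_id in truth.planted_regulators.items():
        up = [g for g, s in truth.signature_signs[k].items() if s > 0]
        down = [g for g, s in truth.signature_signs[k].items() if s < 0]
        n_up = min(len(up), int(np.ceil(0.7 * config.regulon_size)))
        n_down = min(len(down), config.regulon_size - n_up)
        targets = list(rng.choice(up, size=n_up, replace=False)) + \
            list(rng.choice(down, size=n_down, replace=False))
        modes = np.concatenate([np.ones(n_up), -np.ones(n_down)])
        out.add(Regulon(
            regulator=reg_id,
            targets=targets,
            modes=modes,
            likelihoods=rng.uniform(0.5, 1.0, size=len(targets)),
        ))
    for d in range(config.n_decoy_regulons):
        targets = list(rng.choice(all_genes, size=config.regulon_size, replace=False))
        out.add(Regulon(
            regulator=f"DECOY_{d}",
            targets=targets,
            modes=rng.choice([-1.0, 1.0], size=len(targets)),
            likelihoods=rng.uniform(0.5, 1.0, size=len(targets)),
        ))
    return out
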