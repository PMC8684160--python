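"""Readers, writers and container types for the on-disk formats.

All matrices are tab-separated text with the feature identifier in the
first column and sample identifiers as the header row.  Copy-number
segments use the SEG dialect (1-based inclusive coordinates on disk,
0-based half-open in memory).  Gene sets are GMT; regulons are a
4-column TSV (regulator, target, mode, likelihood).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CNV_CALLS = ("loss", "neutral", "gain")

SV_FLAGS = ("t(4;14)", "t(11;14)", "t(14;16)", "HY")


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass
class CnvSegmentProfile:
    """Copy-number segments for one sample.

    Segments are ``(chromosome, start, end, call)`` with 0-based
    half-open coordinates and ``call`` in :data:`CNV_CALLS`.
    ``genome_size`` is the total callable genome length in bp and is the
    denominator of the genomic-loss fraction.
    """

    sample_id: str
    segments: list[tuple[str, int, int, str]]
    genome_size: int

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ValueError(f"genome_size must be positive, got {self.genome_size}")
        for chrom, start, end, call in self.segments:
            if start >= end:
                raise DataFormatError(
                    f"sample {self.sample_id}: segment {chrom}:{start}-{end} has start >= end"
                )
            if call not in CNV_CALLS:
                raise DataFormatError(
                    f"sample {self.sample_id}: unknown CNV call {call!r}"
                )


@dataclass
class SurvivalTable:
    """Per-sample time-to-event outcomes with optional covariates.

    ``time`` is in months and must be positive; ``event`` is 1 for an
    observed event and 0 for censoring.  Extra columns are covariates
    (ISS stage dummies, marker flags, subgroup membership, ...).
    """

    data: pd.DataFrame  # index = sample ids; columns: time, event, covariates...

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise DataFormatError("survival table requires 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            bad = self.data.index[self.data["time"] <= 0].tolist()
            raise DataFormatError(f"non-positive times for samples: {bad[:5]}")
        if not self.data["event"].isin([0, 1]).all():
            raise DataFormatError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(int)

    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])


@dataclass
class Regulon:
    """A regulator's weighted, signed target set.

    ``mode`` in [-1, 1] is the inferred direction of regulation;
    ``likelihood`` in (0, 1] the confidence weight of each interaction.
    """

    regulator: str
    targets: list[str]
    modes: np.ndarray
    likelihoods: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.targets)) != len(self.targets):
            raise DataFormatError(f"regulon {self.regulator}: duplicate targets")
        self.modes = np.asarray(self.modes, float)
        self.likelihoods = np.asarray(self.likelihoods, float)
        if np.any(np.abs(self.modes) > 1):
            raise DataFormatError(f"regulon {self.regulator}: mode outside [-1, 1]")
        if np.any((self.likelihoods <= 0) | (self.likelihoods > 1)):
            raise DataFormatError(
                f"regulon {self.regulator}: likelihood outside (0, 1]"
            )

    def __len__(self) -> int:
        return len(self.targets)


class RegulonSet(dict):
    """Mapping regulator id -> :class:`Regulon`."""

    def add(self, regulon: Regulon) -> None:
        self[regulon.regulator] = regulon


@dataclass
class MultiOmicsDataset:
    """Sample-aligned omics layers.

    expression : genes x samples, TPM-like non-negative values
    cnv_states : cytobands x samples integer copy states (2 = neutral)
    mutations  : genes x samples binary missense indicator
    sv_flags   : flags x samples binary structural-variant indicator
    """

    expression: pd.DataFrame
    cnv_states: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    sv_flags: pd.DataFrame | None = None
    # segment-level CNV calls, kept alongside the cytoband summary so the
    # genomic-loss statistic can be recomputed from the raw segments
    cnv_profiles: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        ref = list(self.expression.columns)
        if len(set(ref)) != len(ref):
            raise DataFormatError("duplicate sample ids in expression layer")
        if (self.expression.to_numpy() < 0).any():
            raise DataFormatError("expression must be non-negative")
        for name, layer in self.layers().items():
            if list(layer.columns) != ref:
                raise DataFormatError(
                    f"layer {name!r} sample ordering differs from expression"
                )
            if layer.index.duplicated().any():
                dups = layer.index[layer.index.duplicated()].tolist()
                raise DataFormatError(f"layer {name!r}: duplicate feature ids {dups[:5]}")

    def layers(self) -> dict[str, pd.DataFrame]:
        out = {"expression": self.expression}
        if self.cnv_states is not None:
            out["cnv"] = self.cnv_states
        if self.mutations is not None:
            out["mutations"] = self.mutations
        if self.sv_flags is not None:
            out["sv"] = self.sv_flags
        return out

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


def assemble_dataset(
    expression: pd.DataFrame,
    cnv_states: pd.DataFrame | None = None,
    mutations: pd.DataFrame | None = None,
    sv_flags: pd.DataFrame | None = None,
    intersect: bool = False,
) -> MultiOmicsDataset:
    """Align layers on a common sample set.

    With ``intersect=False`` any mismatch between sample sets raises,
    listing the offending samples.  With ``intersect=True`` the layers
    are restricted to the intersection of their sample sets and dropped
    samples are reported in the log.
    """
    named = {"expression": expression, "cnv": cnv_states,
             "mutations": mutations, "sv": sv_flags}
    present = {k: v for k, v in named.items() if v is not None}
    sets = {k: set(v.columns) for k, v in present.items()}
    common = set.intersection(*sets.values())
    union = set.union(*sets.values())
    if not intersect and common != union:
        offenders = {k: sorted(union - s) for k, s in sets.items() if union - s}
        raise DataFormatError(
            "sample sets differ across layers (pass intersect=True to keep the "
            f"common subset); missing per layer: {offenders}"
        )
    dropped = sorted(union - common)
    if dropped:
        logger.info("dropping %d unmatched samples: %s", len(dropped), dropped[:10])
    order = [s for s in expression.columns if s in common]
    aligned = {k: v[order] for k, v in present.items()}
    return MultiOmicsDataset(
        expression=aligned["expression"],
        cnv_states=aligned.get("cnv"),
        mutations=aligned.get("mutations"),
        sv_flags=aligned.get("sv"),
    )


# ---------------------------------------------------------------------------
# matrix TSV
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column feature id)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = [s for s, c in pd.Series(header).value_counts().items() if c > 1]
    if dups:
        raise DataFormatError(f"{path.name}: duplicate sample columns {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise DataFormatError(f"{path.name}: duplicate feature ids {dups[:5]}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")


read_expression = read_matrix
write_expression = write_matrix
read_mutations = read_matrix
write_mutations = write_matrix


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "call"]


def read_seg(path: str | Path, genome_size: int) -> dict[str, CnvSegmentProfile]:
    """Read SEG-style segment calls into per-sample profiles.

    On-disk coordinates are 1-based inclusive; in memory they become
    0-based half-open.  Malformed rows raise an error naming the line.
    """
    path = Path(path)
    profiles: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.lower() for h in header] != _SEG_COLUMNS:
            raise DataFormatError(
                f"{path.name}: expected header {_SEG_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise DataFormatError(f"{path.name}:{lineno}: expected 5 fields")
            sample, chrom, start_s, end_s, call = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataFormatError(
                    f"{path.name}:{lineno}: non-integer coordinate"
                ) from exc
            if end1 < start1:
                raise DataFormatError(
                    f"{path.name}:{lineno}: end < start ({end1} < {start1})"
                )
            if call not in CNV_CALLS:
                raise DataFormatError(f"{path.name}:{lineno}: unknown call {call!r}")
            profiles.setdefault(sample, []).append((chrom, start1 - 1, end1, call))
    return {
        s: CnvSegmentProfile(sample_id=s, segments=segs, genome_size=genome_size)
        for s, segs in profiles.items()
    }


def write_seg(profiles: Iterable[CnvSegmentProfile], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for prof in profiles:
            for chrom, start, end, call in prof.segments:
                fh.write(f"{prof.sample_id}\t{chrom}\t{start + 1}\t{end}\t{call}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name, description, then member genes."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 fields"
                )
            name, _desc, *genes = fields
            if name in sets:
                raise DataFormatError(f"{path.name}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\t.\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# regulons
# ---------------------------------------------------------------------------


def read_regulons(path: str | Path) -> RegulonSet:
    """Read the 4-column regulon TSV (regulator, target, mode, likelihood)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = ["regulator", "target", "mode", "likelihood"]
    if list(df.columns) != expected:
        raise DataFormatError(f"{path.name}: expected columns {expected}")
    out = RegulonSet()
    for reg, grp in df.groupby("regulator", sort=False):
        out.add(
            Regulon(
                regulator=str(reg),
                targets=[str(t) for t in grp["target"]],
                modes=grp["mode"].to_numpy(float),
                likelihoods=grp["likelihood"].to_numpy(float),
            )
        )
    return out


def regulons_from_gmt(sets: Mapping[str, Sequence[str]]) -> RegulonSet:
    """Lift unsigned GMT sets to regulons with mode=+1, likelihood=1."""
    out = RegulonSet()
    for name, genes in sets.items():
        genes = list(dict.fromkeys(genes))
        out.add(
            Regulon(
                regulator=name,
                targets=list(genes),
                modes=np.ones(len(genes)),
                likelihoods=np.ones(len(genes)),
            )
        )
    return out


def write_regulons(regulons: RegulonSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for reg in regulons.values():
        for t, m, lk in zip(reg.targets, reg.modes, reg.likelihoods):
            rows.append((reg.regulator, t, m, lk))
    pd.DataFrame(rows, columns=["regulator", "target", "mode", "likelihood"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path) -> SurvivalTable:
    """Read the clinical TSV: sample, time, event[, covariates...]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise DataFormatError(f"{path.name}: first column must be 'sample'")
    if df["sample"].duplicated().any():
        raise DataFormatError(f"{path.name}: duplicate sample ids")
    df = df.set_index("sample")
    return SurvivalTable(df)


def write_clinical(table: SurvivalTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


# ---------------------------------------------------------------------------
# cytoband map
# ---------------------------------------------------------------------------


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Read a cytoband map TSV with columns chrom, start, end, band."""
    df = pd.read_csv(path, sep="\t")
    expected = ["chrom", "start", "end", "band"]
    if list(df.columns) != expected:
        raise DataFormatError(f"cytoband map needs columns {expected}")
    if (df["start"] >= df["end"]).any():
        raise DataFormatError("cytoband with start >= end")
    if df["band"].duplicated().any():
        raise DataFormatError("duplicate cytoband ids")
    return df


def write_cytobands(bands: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    bands.to_csv(path, sep="\t", index=False)
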