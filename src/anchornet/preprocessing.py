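"""Expression and genomic-feature preprocessing for CAGE-like data.

Implements the standard processing rules for FANTOM5-style tables:

* genes are kept when they reach TPM >= 1 in at least one sample, then
  log2(TPM + 1)-transformed;
* enhancers are kept when expressed (non-zero) in strictly more than one
  third of samples, and stay on the raw TPM scale (the rank transform used
  downstream is scale-free anyway);
* each TF is represented by its promoter with the highest median expression;
* candidate anchor enhancers are those whose midpoint lies within 50 kb of
  the TF's TSS;
* enhancer vectors are binarized as zero / non-zero;
* ground-truth target sets come from ChIP peaks within 1 kb of a gene TSS or
  from knock-out differential expression at q < 0.05.

Coordinates follow the BED convention (0-based, half-open); TSS features are
1-bp intervals. Strand is carried but ignored for distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicFeature",
    "TargetSet",
    "EmptyResultError",
    "DEFAULT_ENHANCER_WINDOW",
    "DEFAULT_CHIP_WINDOW",
    "DEFAULT_KO_QVALUE",
    "read_expression",
    "write_expression",
    "read_bed",
    "write_bed",
    "read_tf_promoter_map",
    "read_ko_table",
    "filter_expressed_genes",
    "filter_enhancers",
    "select_tf_promoter",
    "assign_candidate_enhancers",
    "binarize_enhancer",
    "derive_chip_targets",
    "derive_ko_targets",
]

DEFAULT_ENHANCER_WINDOW = 50_000  # bp, enhancer midpoint to TF TSS
DEFAULT_CHIP_WINDOW = 1_000  # bp, ChIP peak to gene TSS
DEFAULT_KO_QVALUE = 0.05


class EmptyResultError(ValueError):
    """A filter removed every feature."""


@dataclass(frozen=True)
class GenomicFeature:
    """BED-convention interval (0-based half-open); TSS have end = start + 1."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) for {self.id}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class TargetSet:
    """A TF's predicted or ground-truth target genes with provenance."""

    tf_id: str
    genes: set = field(default_factory=set)
    source: str = "predicted"

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if self.source not in ("predicted", "chipseq", "knockout", "truth"):
            raise ValueError(f"unknown target-set source {self.source!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a feature-by-sample TSV (first column feature ID, header samples).

    Returns a DataFrame with the feature IDs as index. Values must be
    non-negative and feature IDs unique; gzip input is handled by pandas.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    if df.shape[1] < 5:
        raise ValueError(f"need at least 5 samples, got {df.shape[1]} in {path}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature_id")


def read_bed(path) -> list[GenomicFeature]:
    """Read BED4/BED6 into GenomicFeature records (extra columns ignored)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line with fewer than 4 columns in {path}: {line!r}")
            strand = parts[5] if len(parts) >= 6 else "."
            feats.append(
                GenomicFeature(
                    id=parts[3], chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    strand=strand,
                )
            )
    return feats


def write_bed(features: Iterable[GenomicFeature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t0\t{f.strand}\n")


def read_tf_promoter_map(path) -> dict[str, list[str]]:
    """Two-column TSV mapping TF id -> promoter feature id (one row per pair)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    out: dict[str, list[str]] = {}
    for tf, prom in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(tf, []).append(prom)
    return out


def read_ko_table(path) -> pd.DataFrame:
    """Two-column TSV (gene, q-value) from a knock-out differential test."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df.columns = ["gene", "qvalue"]
    df["qvalue"] = pd.to_numeric(df["qvalue"], errors="raise")
    if ((df["qvalue"] < 0) | (df["qvalue"] > 1)).any():
        raise ValueError(f"q-values outside [0, 1] in {path}")
    return df


# ---------------------------------------------------------------------------
# filters and selections
# ---------------------------------------------------------------------------

def filter_expressed_genes(
    m: pd.DataFrame, min_tpm: float = 1.0, log_transform: bool = True, log_base: float = 2.0,
) -> pd.DataFrame:
    """Keep genes with TPM >= ``min_tpm`` in at least one sample; log-transform.

    The retained rows become log2(TPM + 1) (base and pseudocount 1 are the
    package's convention). Idempotence note: the filter rule is applied to
    whatever scale it is given, so apply it once to raw TPM.
    """
    if m.shape[0] == 0:
        raise EmptyResultError("empty expression matrix")
    keep = (m.max(axis=1) >= min_tpm).to_numpy()
    if not keep.any():
        raise EmptyResultError("no gene reaches the expression threshold")
    out = m.loc[keep]
    if log_transform:
        out = np.log(out + 1.0) / np.log(log_base)
    return out


def filter_enhancers(m: pd.DataFrame) -> pd.DataFrame:
    """Keep enhancers non-zero in strictly more than one third of samples.

    Values are deliberately left on the raw TPM scale: the continuous-anchor
    method consumes untransformed eRNA values (its rank transform makes any
    monotone rescaling immaterial), and the binary path needs the zeros.
    """
    if m.shape[0] == 0:
        raise EmptyResultError("empty enhancer matrix")
    n = m.shape[1]
    keep = ((m > 0).sum(axis=1) > n / 3.0).to_numpy()
    if not keep.any():
        raise EmptyResultError("no enhancer passes the expression filter")
    return m.loc[keep]


def select_tf_promoter(promoter_rows: pd.DataFrame) -> str:
    """ID of the promoter with the highest median expression (ties: lexicographic)."""
    if promoter_rows.shape[0] == 0:
        raise ValueError("no promoter rows given")
    med = promoter_rows.median(axis=1)
    best = med.max()
    return sorted(med.index[med == best])[0]


def assign_candidate_enhancers(
    tss: GenomicFeature,
    enhancers: Sequence[GenomicFeature],
    window: int = DEFAULT_ENHANCER_WINDOW,
) -> list[tuple[str, float]]:
    """Enhancers whose midpoint is within ``window`` bp (inclusive) of the TSS.

    Distance is |enhancer midpoint - TSS position|; results are sorted by
    distance then ID, so the output is invariant to input order.
    """
    pos = tss.start
    out = []
    for enh in enhancers:
        if enh.chrom != tss.chrom:
            continue
        d = abs(enh.midpoint - pos)
        if d <= window:
            out.append((enh.id, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


def binarize_enhancer(raw) -> np.ndarray:
    """0 where TPM == 0 exactly, 1 elsewhere (degenerate vectors pass through;
    they are flagged when used as anchors)."""
    raw = np.asarray(raw, dtype=float)
    if (raw < 0).any():
        raise ValueError("negative expression values")
    return (raw != 0).astype(int)


def derive_chip_targets(
    peaks: Sequence[GenomicFeature],
    tss_table: Sequence[GenomicFeature],
    tf_id: str,
    window: int = DEFAULT_CHIP_WINDOW,
) -> TargetSet:
    """Genes with a ChIP peak within ``window`` bp (inclusive) of their TSS.

    Gap distance is 0 when the TSS lies inside a peak.
    """
    if not peaks:
        warnings.warn(f"no ChIP peaks for {tf_id}; empty target set", stacklevel=2)
        return TargetSet(tf_id=tf_id, genes=set(), source="chipseq")
    by_chrom: dict[str, list[GenomicFeature]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    genes = set()
    for tss in tss_table:
        pos = tss.start
        for p in by_chrom.get(tss.chrom, ()):
            # gap between a point and a half-open interval [start, end)
            gap = max(p.start - pos, pos - (p.end - 1), 0)
            if gap <= window:
                genes.add(tss.id)
                break
    return TargetSet(tf_id=tf_id, genes=genes, source="chipseq")


def derive_ko_targets(
    de_table: pd.DataFrame, tf_id: str, max_qvalue: float = DEFAULT_KO_QVALUE
) -> TargetSet:
    """Genes with differential-expression q-value strictly below the cutoff."""
    if de_table.shape[0] == 0:
        warnings.warn(f"empty knock-out table for {tf_id}", stacklevel=2)
        return TargetSet(tf_id=tf_id, genes=set(), source="knockout")
    q = pd.to_numeric(de_table["qvalue"], errors="raise")
    if q.isna().any() or ((q < 0) | (q > 1)).any():
        raise ValueError("malformed q-values")
    genes = set(de_table.loc[(q < max_qvalue).to_numpy(), "gene"].astype(str))
    return TargetSet(tf_id=tf_id, genes=genes, source="knockout")
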