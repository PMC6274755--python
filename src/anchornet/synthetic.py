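"""Seeded generator of CAGE-like datasets with known causal structure.

Each transcription factor (TF) gets one causal enhancer and a number of
decoy enhancers. Latent variables follow the anchored chain with explicit
confounding:

    E_j  (anchor)      zero-inflated eRNA signal, binary (on/off Bernoulli)
                       or continuous (left-censored log-normal) truth
    A_j  (TF)          effect_ea * E_j + confounder_strength * C_j + noise
    B    (true target) effect_ab * A_j + confounder_strength * C_j + noise
    B'   (foil)        direct E_j effect on a fraction of non-targets
                       (pleiotropy; what the controlled test must reject)

with C_j a shared standard-normal confounder and unit-variance Gaussian
noise throughout. Latent gene values are mapped to a TPM-like positive
scale by exponentiation; enhancer vectors keep exact zeros so the binary
encoding is meaningful. Equal seeds give bit-identical output.

The ``confounded-network`` preset is the package's benchmark bed; the
``binary-anchors`` / ``continuous-anchors`` presets probe adaptive mode
selection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import GenomicFeature, TargetSet, write_bed, write_expression

__all__ = ["ScenarioSpec", "SyntheticDataset", "PRESETS", "simulate_dataset", "write_fixture", "read_truth"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic study.

    Defaults are the ``confounded-network`` benchmark: 50 samples (a typical
    FANTOM5 per-cell-type series), 10 TFs with 100 true targets each among
    2000 candidate genes, anchor->TF effect 0.8, TF->target effect 0.6,
    confounder strength 0.4, 10% pleiotropic foils and 30% enhancer
    zero-inflation.
    """

    n_samples: int = 50
    n_tfs: int = 10
    n_genes: int = 2000
    targets_per_tf: int = 100
    effect_ea: float = 0.8
    effect_ab: float = 0.6
    confounder_strength: float = 0.4
    pleiotropy_fraction: float = 0.1
    enhancer_zero_inflation: float = 0.3
    anchor_mode_truth: str = "mixed"  # continuous | binary | mixed
    decoys_per_tf: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_tfs, self.n_genes, self.targets_per_tf) <= 0:
            raise ValueError("counts must be positive")
        if self.n_samples < 5:
            raise ValueError("need at least 5 samples")
        for name in ("pleiotropy_fraction", "enhancer_zero_inflation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.anchor_mode_truth not in ("continuous", "binary", "mixed"):
            raise ValueError(f"unknown anchor_mode_truth {self.anchor_mode_truth!r}")
        if self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ValueError("more true targets than genes")


@dataclass
class SyntheticDataset:
    """A simulated study plus its ground truth."""

    spec: ScenarioSpec
    enhancers: pd.DataFrame  # raw TPM-like, with exact zeros
    genes: pd.DataFrame  # raw TPM-like (TF promoter rows included)
    truth: list[TargetSet] = field(default_factory=list)
    anchor_map: dict = field(default_factory=dict)  # tf -> candidate enhancer ids
    causal_enhancer: dict = field(default_factory=dict)  # tf -> its causal enhancer
    mode_truth: dict = field(default_factory=dict)  # tf -> "continuous"|"binary"

    @property
    def tf_ids(self) -> list[str]:
        return list(self.anchor_map)


# lognormal parameters of the observed TPM scales (log-TPM mean and sd)
_ENH_LOG_MU, _ENH_LOG_SD = 1.0, 0.5
_GENE_LOG_MU, _GENE_LOG_SD = 2.0, 0.5


def _sample_anchor(rng: np.random.Generator, n: int, mode: str, zero_inflation: float):
    """(latent unit-variance anchor, observed TPM vector with exact zeros)."""
    if mode == "binary":
        while True:
            on = rng.random(n) >= zero_inflation
            if 0 < on.sum() < n:
                break
        latent = (on - on.mean()) / on.std()
        obs = np.where(on, np.exp(_ENH_LOG_MU + _ENH_LOG_SD * rng.standard_normal(n)), 0.0)
        return latent, obs
    # continuous truth: log-normal eRNA left-censored to zero below the
    # zero_inflation quantile; the latent (uncensored) value drives the TF
    cut = stats.norm.ppf(zero_inflation) if zero_inflation > 0 else -np.inf
    while True:
        g = rng.standard_normal(n)
        obs = np.where(g >= cut, np.exp(_ENH_LOG_MU + _ENH_LOG_SD * g), 0.0)
        if np.ptp(obs) > 0:
            break
    return g, obs


def simulate_dataset(spec: ScenarioSpec) -> SyntheticDataset:
    """Simulate one study; bit-identical for equal specs (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    tf_ids = [f"TF{j+1:02d}" for j in range(spec.n_tfs)]
    gene_ids = [f"G{i+1:04d}" for i in range(spec.n_genes)]

    if spec.anchor_mode_truth == "mixed":
        modes = ["binary" if j % 2 else "continuous" for j in range(spec.n_tfs)]
    else:
        modes = [spec.anchor_mode_truth] * spec.n_tfs

    # disjoint true-target blocks, then pleiotropic foils among the rest
    perm = rng.permutation(spec.n_genes)
    truth_idx = {
        tf: np.sort(perm[j * spec.targets_per_tf : (j + 1) * spec.targets_per_tf])
        for j, tf in enumerate(tf_ids)
    }
    rest = np.sort(perm[spec.n_tfs * spec.targets_per_tf :])
    n_pleio = int(round(spec.pleiotropy_fraction * rest.size))
    pleio_idx = np.sort(rng.choice(rest, size=n_pleio, replace=False)) if n_pleio else np.array([], int)
    pleio_tf = rng.integers(0, spec.n_tfs, size=n_pleio)

    gene_latent = rng.standard_normal((spec.n_genes, n))  # per-gene noise
    enh_rows = {}
    anchor_map: dict[str, list[str]] = {}
    causal = {}
    mode_truth = {}
    tf_latent = {}

    for j, tf in enumerate(tf_ids):
        e_latent, e_obs = _sample_anchor(rng, n, modes[j], spec.enhancer_zero_inflation)
        conf = rng.standard_normal(n)
        a = spec.effect_ea * e_latent + spec.confounder_strength * conf + rng.standard_normal(n)
        tf_latent[tf] = a
        eid = f"E{j+1:02d}.causal"
        enh_rows[eid] = e_obs
        anchor_map[tf] = [eid]
        causal[tf] = eid
        mode_truth[tf] = modes[j]
        for d in range(spec.decoys_per_tf):
            _, decoy_obs = _sample_anchor(
                rng, n, modes[j], spec.enhancer_zero_inflation
            )
            did = f"E{j+1:02d}.decoy{d+1}"
            enh_rows[did] = decoy_obs
            anchor_map[tf].append(did)
        # true targets: chain through A with shared confounder
        idx = truth_idx[tf]
        gene_latent[idx] += spec.effect_ab * a + spec.confounder_strength * conf
        # pleiotropic foils: direct anchor effect, no A->B edge
        foils = pleio_idx[pleio_tf == j]
        if foils.size:
            gene_latent[foils] += spec.effect_ea * spec.effect_ab * e_latent

    # clip log-TPM so extreme effect sizes cannot overflow to inf
    genes = np.exp(np.clip(_GENE_LOG_MU + _GENE_LOG_SD * gene_latent, -50.0, 50.0))
    gene_df = pd.DataFrame(genes, index=gene_ids,
                           columns=[f"S{i+1:03d}" for i in range(n)])
    # TF promoter rows on the same TPM-like scale
    for tf in tf_ids:
        gene_df.loc[tf] = np.exp(np.clip(_GENE_LOG_MU + _GENE_LOG_SD * tf_latent[tf], -50.0, 50.0))
    enh_df = pd.DataFrame.from_dict(enh_rows, orient="index")
    enh_df.columns = gene_df.columns
    enh_df.index.name = "enhancer_id"
    gene_df.index.name = "gene_id"

    truth = [
        TargetSet(tf_id=tf, genes={gene_ids[i] for i in truth_idx[tf]}, source="truth")
        for tf in tf_ids
    ]
    return SyntheticDataset(
        spec=spec, enhancers=enh_df, genes=gene_df, truth=truth,
        anchor_map=anchor_map, causal_enhancer=causal, mode_truth=mode_truth,
    )


PRESETS: dict[str, ScenarioSpec] = {
    "confounded-network": ScenarioSpec(),
    "binary-anchors": ScenarioSpec(anchor_mode_truth="binary"),
    "continuous-anchors": ScenarioSpec(anchor_mode_truth="continuous"),
    # no TF->target signal at all: effect, shared confounding and pleiotropy off
    "null": ScenarioSpec(effect_ab=0.0, confounder_strength=0.0, pleiotropy_fraction=0.0),
    "toy": ScenarioSpec(n_samples=30, n_tfs=3, n_genes=200, targets_per_tf=20),
}


_TSS_POS = 1_000_000
_ENH_SPACING = 10_000
_FAR_OFFSET = 60_000  # beyond the 50 kb window on purpose


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write a dataset in the exact dialects the preprocessing readers use.

    Layout: ``genes.tsv`` and ``enhancers.tsv`` (TPM matrices),
    ``tf_tss.bed`` (1-bp TSS per TF promoter), ``enhancers.bed`` (each TF's
    candidate enhancers inside the 50 kb window, plus one far decoy placed
    60 kb away per TF), ``tf_promoters.tsv``, ``truth/<tf>.txt`` target
    lists and ``scenario.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genes"] = directory / "genes.tsv"
    write_expression(dataset.genes, paths["genes"])
    paths["enhancers"] = directory / "enhancers.tsv"

    tss_feats, enh_feats, prom_rows = [], [], []
    rng = np.random.default_rng(dataset.spec.seed + 1)
    for j, tf in enumerate(dataset.tf_ids):
        chrom = f"chr{j+1}"
        tss_feats.append(GenomicFeature(id=tf, chrom=chrom, start=_TSS_POS, end=_TSS_POS + 1))
        prom_rows.append((tf, tf))
        for k, eid in enumerate(dataset.anchor_map[tf]):
            mid = _TSS_POS + (k + 1) * _ENH_SPACING * (1 if k % 2 == 0 else -1)
            enh_feats.append(GenomicFeature(id=eid, chrom=chrom, start=mid - 500, end=mid + 500))
        # an out-of-window enhancer: independent noise the window must drop
        far_id = f"E{j+1:02d}.far"
        far_obs = np.where(
            rng.random(dataset.spec.n_samples) >= 0.5,
            np.exp(rng.standard_normal(dataset.spec.n_samples)), 0.0,
        )
        dataset.enhancers.loc[far_id] = far_obs
        enh_feats.append(
            GenomicFeature(id=far_id, chrom=chrom,
                           start=_TSS_POS + _FAR_OFFSET - 500, end=_TSS_POS + _FAR_OFFSET + 500)
        )
    write_expression(dataset.enhancers, paths["enhancers"])  # includes far rows

    paths["tf_tss"] = directory / "tf_tss.bed"
    write_bed(tss_feats, paths["tf_tss"])
    paths["enhancers_bed"] = directory / "enhancers.bed"
    write_bed(enh_feats, paths["enhancers_bed"])
    paths["tf_promoters"] = directory / "tf_promoters.tsv"
    pd.DataFrame(prom_rows, columns=["tf_id", "promoter_id"]).to_csv(
        paths["tf_promoters"], sep="\t", index=False
    )

    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    for ts in dataset.truth:
        with open(truth_dir / f"{ts.tf_id}.txt", "w") as fh:
            fh.write("\n".join(sorted(ts.genes)) + "\n")
    paths["truth"] = truth_dir

    paths["scenario"] = directory / "scenario.json"
    with open(paths["scenario"], "w") as fh:
        json.dump(asdict(dataset.spec), fh, indent=2)
    return paths


def read_truth(truth_dir) -> dict[str, TargetSet]:
    """Read ``truth/<tf>.txt`` lists back into TargetSets."""
    out = {}
    for path in sorted(Path(truth_dir).glob("*.txt")):
        tf = path.stem
        genes = {line.strip() for line in path.read_text().splitlines() if line.strip()}
        out[tf] = TargetSet(tf_id=tf, genes=genes, source="truth")
    return out
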