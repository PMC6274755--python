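"""Model / results interface for enhancer-anchored causal network inference.

``CausalAnchorModel`` is built from a gene expression table, an enhancer
expression table and a per-TF list of candidate anchor enhancers; ``fit()``
returns a ``CausalAnchorResults`` carrying the per-(TF, gene) combined
causality scores, the selected anchor for each TF, and diagnostics.

Example
-------
>>> model = CausalAnchorModel(genes, enhancers, tf_enhancers, mode="adaptive")
>>> res = model.fit()
>>> print(res.summary())
>>> hits = res.threshold(0.8)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, preprocessing
from .inference import (
    DEFAULT_PRIMARY_ALPHA,
    SCORE_COLUMNS,
    AnchorCandidate,
    NoAnchorError,
)
from .preprocessing import TargetSet

__all__ = ["CausalAnchorModel", "CausalAnchorResults"]


class CausalAnchorModel:
    """Per-TF causal target prediction from expression with enhancer anchors.

    Parameters
    ----------
    gene_expr : DataFrame (genes x samples)
        Expression of promoters/genes, already filtered and log-transformed
        (see :func:`anchornet.preprocessing.filter_expressed_genes`); the
        rank transform applied internally makes the scale immaterial.
    enhancer_expr : DataFrame (enhancers x samples)
        Raw (untransformed) eRNA TPM values; zeros are meaningful because
        they define the binary encoding.
    tf_enhancers : mapping tf_id -> sequence of enhancer ids
        Candidate causal-anchor enhancers per TF (typically the enhancers
        within 50 kb of the TF's TSS). TF ids must be rows of ``gene_expr``.
    mode : {"adaptive", "continuous", "binary"}
        Anchor treatment: adaptive picks per TF the (enhancer, encoding)
        with the strongest primary linkage; the fixed modes restrict the
        choice to one encoding.
    combination : {"default", "traditional"}
        Combined score 1/2 (P2 P5 + P4), or the conditional-independence
        baseline P2 P3.
    primary_alpha : float
        A TF is skipped (with a diagnostic record) when its best
        primary-linkage p-value exceeds this.
    """

    def __init__(
        self,
        gene_expr: pd.DataFrame,
        enhancer_expr: pd.DataFrame,
        tf_enhancers: dict,
        mode: str = "adaptive",
        combination: str = "default",
        primary_alpha: float = DEFAULT_PRIMARY_ALPHA,
    ) -> None:
        if mode not in ("adaptive", "continuous", "binary"):
            raise ValueError(f"unknown mode {mode!r}")
        if combination not in ("default", "traditional"):
            raise ValueError(f"unknown combination {combination!r}")
        if list(gene_expr.columns) != list(enhancer_expr.columns):
            raise ValueError("gene and enhancer tables must share the same samples")
        missing = [tf for tf in tf_enhancers if tf not in gene_expr.index]
        if missing:
            raise ValueError(f"TFs absent from gene table: {missing[:5]}")
        self.gene_expr = gene_expr
        self.enhancer_expr = enhancer_expr
        self.tf_enhancers = {tf: list(enhs) for tf, enhs in tf_enhancers.items()}
        self.mode = mode
        self.combination = combination
        self.primary_alpha = primary_alpha

    @classmethod
    def from_fixture(cls, directory, **kwargs) -> "CausalAnchorModel":
        """Build a model from an on-disk dataset in the package's file layout.

        Expects ``genes.tsv`` (raw TPM), ``enhancers.tsv`` (raw TPM),
        ``tf_tss.bed``, ``enhancers.bed`` and ``tf_promoters.tsv`` in
        ``directory``; applies the expression filters, promoter selection and
        the 50 kb candidate-enhancer window.
        """
        directory = Path(directory)
        genes_raw = preprocessing.read_expression(directory / "genes.tsv")
        enh_raw = preprocessing.read_expression(directory / "enhancers.tsv")
        genes = preprocessing.filter_expressed_genes(genes_raw)
        enhancers = preprocessing.filter_enhancers(enh_raw)
        tss = {f.id: f for f in preprocessing.read_bed(directory / "tf_tss.bed")}
        enh_feats = preprocessing.read_bed(directory / "enhancers.bed")
        prom_map = preprocessing.read_tf_promoter_map(directory / "tf_promoters.tsv")

        tf_enhancers = {}
        for tf, promoters in prom_map.items():
            rows = [p for p in promoters if p in genes.index]
            if not rows:
                continue
            promoter = preprocessing.select_tf_promoter(genes.loc[rows])
            if promoter not in tss:
                continue
            cands = preprocessing.assign_candidate_enhancers(tss[promoter], enh_feats)
            ids = [eid for eid, _ in cands if eid in enhancers.index]
            if ids:
                # model rows are promoter feature ids; keep the TF keyed by it
                tf_enhancers[promoter] = ids
        return cls(genes, enhancers, tf_enhancers, **kwargs)

    def fit(self) -> "CausalAnchorResults":
        """Select anchors and score all candidate targets for every TF."""
        score_frames = []
        anchor_records = []
        for tf in sorted(self.tf_enhancers):
            enh_ids = [e for e in self.tf_enhancers[tf] if e in self.enhancer_expr.index]
            record = {"tf": tf, "enhancer": None, "mode": None, "primary_pvalue": np.nan,
                      "n_candidates": 0, "fitted": False, "reason": ""}
            if not enh_ids:
                record["reason"] = "no candidate enhancers in expression table"
                anchor_records.append(record)
                continue
            tf_vec = self.gene_expr.loc[tf].to_numpy(dtype=float)
            candidates = inference.build_anchor_candidates(
                self.enhancer_expr.loc[enh_ids], tf_vec
            )
            if self.mode != "adaptive":
                candidates = [c for c in candidates if c.mode == self.mode]
            record["n_candidates"] = len(candidates)
            try:
                enh_id, enc_mode = inference.select_anchor_adaptive(candidates)
            except NoAnchorError:
                record["reason"] = "all anchor encodings degenerate"
                anchor_records.append(record)
                continue
            best_p = min(c.primary_pvalue for c in candidates)
            record.update(enhancer=enh_id, mode=enc_mode, primary_pvalue=best_p)
            if best_p > self.primary_alpha:
                record["reason"] = "primary linkage not significant"
                anchor_records.append(record)
                continue

            targets = self.gene_expr.drop(index=tf)
            stats = inference.predict_targets(
                self.enhancer_expr.loc[enh_id].to_numpy(dtype=float),
                tf_vec,
                targets,
                mode=enc_mode,
                combination=self.combination,
            )
            frame = stats.reset_index(names="gene")
            frame.insert(0, "tf", tf)
            frame.insert(1, "enhancer", enh_id)
            frame.insert(2, "mode", enc_mode)
            score_frames.append(frame)
            record["fitted"] = True
            anchor_records.append(record)

        if score_frames:
            scores = pd.concat(score_frames, ignore_index=True)
        else:
            scores = pd.DataFrame(
                columns=["tf", "enhancer", "mode", "gene"]
                + [f"{k}{t}" for t in (2, 3, 4, 5) for k in ("llr", "p", "P")]
                + ["combined"]
            )
        anchors = pd.DataFrame.from_records(anchor_records).set_index("tf") if (
            anchor_records
        ) else pd.DataFrame()
        return CausalAnchorResults(model=self, scores=scores, anchors=anchors)


@dataclass
class CausalAnchorResults:
    """Fitted scores: one row per (TF, candidate gene) with tests 2-5.

    ``scores`` columns: tf, enhancer, mode, gene, llr/p/P per test and the
    ``combined`` causality score in [0, 1]. ``anchors`` records per TF the
    selected enhancer and encoding, the best primary-linkage p-value and why
    a TF was skipped, if it was.
    """

    model: CausalAnchorModel
    scores: pd.DataFrame
    anchors: pd.DataFrame

    @property
    def fitted_tfs(self) -> list[str]:
        if self.anchors.empty:
            return []
        return list(self.anchors.index[self.anchors["fitted"]])

    def score_matrix(self) -> pd.DataFrame:
        """Wide gene x TF matrix of combined scores (NaN where unscored)."""
        return self.scores.pivot(index="gene", columns="tf", values="combined")

    def threshold(self, threshold: float = 0.8) -> list[TargetSet]:
        """Predicted target sets: genes with combined score strictly above."""
        from .evaluation import threshold_predictions

        return threshold_predictions(self.scores, threshold=threshold)

    def summary(self) -> str:
        """Human-readable per-TF fit summary."""
        from statsmodels.iolib.table import SimpleTable

        rows = []
        for tf, rec in self.anchors.iterrows():
            sub = self.scores[self.scores["tf"] == tf]
            n_hits = int((sub["combined"] > 0.8).sum()) if len(sub) else 0
            rows.append(
                [
                    tf,
                    rec["enhancer"] or "-",
                    rec["mode"] or "-",
                    "-" if np.isnan(rec["primary_pvalue"]) else f"{rec['primary_pvalue']:.3g}",
                    str(len(sub)),
                    str(n_hits),
                    "yes" if rec["fitted"] else f"no ({rec['reason']})",
                ]
            )
        table = SimpleTable(
            rows,
            headers=["TF", "anchor", "mode", "primary p", "targets scored", "score>0.8", "fitted"],
            title=f"Causal anchor inference ({self.model.mode} mode, "
            f"{self.model.combination} combination)",
        )
        return table.as_text()

    def to_tsv(self, directory) -> None:
        """Write the long score table and the wide gene x TF matrix."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        inference.write_score_table(self.scores, directory / "scores_long.tsv")
        self.score_matrix().to_csv(directory / "scores_matrix.tsv", sep="\t")
        self.anchors.to_csv(directory / "anchors.tsv", sep="\t")
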