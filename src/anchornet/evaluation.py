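"""Validation of predicted targets: thresholding, precision-recall,
hypergeometric enrichment with Benjamini-Hochberg correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import TargetSet

__all__ = [
    "EnrichmentResult",
    "DEFAULT_SCORE_THRESHOLD",
    "threshold_predictions",
    "precision_recall",
    "enrichment_test",
    "enrichment_table",
]

DEFAULT_SCORE_THRESHOLD = 0.8


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of a predicted target set with a ground-truth set."""

    tf_id: str
    overlap: int
    predicted_n: int
    truth_n: int
    universe_n: int
    pvalue: float
    qvalue: float = np.nan

    def __post_init__(self) -> None:
        if self.overlap > min(self.predicted_n, self.truth_n):
            raise ValueError("overlap exceeds set sizes")


def threshold_predictions(
    scores: pd.DataFrame, threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[TargetSet]:
    """Per TF, the genes whose combined score strictly exceeds the threshold.

    ``scores`` is the long table produced by the model (columns tf, gene,
    combined). The cut is strict: a score exactly at the threshold is out.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for tf, sub in scores.groupby("tf", sort=True):
        genes = set(sub.loc[(sub["combined"] > threshold).to_numpy(), "gene"])
        out.append(TargetSet(tf_id=str(tf), genes=genes, source="predicted"))
    return out


def precision_recall(scores, truth) -> dict:
    """Precision-recall curve, step-integral area and background precision.

    Returns ``{"precision", "recall", "thresholds", "auc", "prevalence"}``.
    The area is the interpolation-free step integral
    sum_k (R_k - R_{k-1}) P_k over descending score thresholds (identical to
    average precision); ``prevalence`` is the random-classifier baseline.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if not set(np.unique(truth)) <= {0, 1}:
        raise ValueError("truth must be 0/1")
    pos = int(truth.sum())
    if pos == 0:
        raise ValueError("no positives: recall undefined")
    if pos == truth.size:
        raise ValueError("no negatives")
    from sklearn.metrics import precision_recall_curve

    precision, recall, thresholds = precision_recall_curve(truth, scores)
    # sklearn returns the curve from high to low threshold reversed; the step
    # integral below is threshold-grouping aware (ties handled by grouping)
    auc = float(-np.sum(np.diff(recall) * precision[:-1]))
    return {
        "precision": precision,
        "recall": recall,
        "thresholds": thresholds,
        "auc": auc,
        "prevalence": pos / truth.size,
    }


def enrichment_test(predicted: TargetSet, truth: TargetSet, universe_n: int) -> EnrichmentResult:
    """Upper-tail hypergeometric test P(X >= overlap) for one TF.

    The universe should be the genes actually scored for the TF (after
    expression filtering), with both sets restricted to it beforehand.
    """
    k = len(predicted.genes & truth.genes)
    m, t = len(predicted.genes), len(truth.genes)
    if universe_n < max(m, t):
        raise ValueError("universe smaller than a set")
    p = float(stats.hypergeom.sf(k - 1, universe_n, t, m))
    return EnrichmentResult(
        tf_id=predicted.tf_id, overlap=k, predicted_n=m, truth_n=t,
        universe_n=universe_n, pvalue=min(p, 1.0),
    )


def enrichment_table(
    predicted: list[TargetSet], truth: dict, universe_n: int
) -> pd.DataFrame:
    """Per-TF enrichment with BH-corrected q-values across all TFs in the run.

    ``truth`` maps tf_id -> TargetSet; TFs without a truth set are skipped.
    """
    results = []
    for pred in predicted:
        if pred.tf_id not in truth:
            continue
        results.append(enrichment_test(pred, truth[pred.tf_id], universe_n))
    if not results:
        return pd.DataFrame(
            columns=["tf_id", "overlap", "predicted_n", "truth_n", "universe_n", "pvalue", "qvalue"]
        )
    pvals = [r.pvalue for r in results]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "tf_id": [r.tf_id for r in results],
            "overlap": [r.overlap for r in results],
            "predicted_n": [r.predicted_n for r in results],
            "truth_n": [r.truth_n for r in results],
            "universe_n": universe_n,
            "pvalue": pvals,
            "qvalue": qvals,
        }
    )
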