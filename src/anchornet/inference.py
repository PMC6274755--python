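"""Per-TF causal target prediction and multi-enhancer consensus utilities.

Three prediction flavours share one computational path:

* continuous mode — the enhancer's eRNA vector is rank-normalized and used
  directly as the causal anchor;
* binary mode — the enhancer is reduced to a standardized zero / non-zero
  indicator (the two-category group-mean model);
* adaptive mode — for each TF, every candidate enhancer is tried in both
  modes and the (enhancer, mode) pair with the smallest primary-linkage
  p-value wins; targets are then predicted with that single anchor.

Scores are combined posteriors P = 1/2 (P2 P5 + P4) by default, or the
traditional conditional-independence combination P2 P3 for comparison
(P3 being the posterior probability that conditional independence holds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import anchor_tests as at
from .preprocessing import TargetSet

__all__ = [
    "AnchorCandidate",
    "NoAnchorError",
    "combined_posterior",
    "traditional_posterior",
    "primary_linkage_pvalue",
    "build_anchor_candidates",
    "select_anchor_adaptive",
    "predict_targets",
    "meta_enhancer",
    "consensus_targets_pca",
    "target_set_jaccard_clustering",
    "write_score_table",
]

#: a TF enters inference only when its best primary-linkage p-value is at or
#: below this (the anchor must be significantly linked to the TF)
DEFAULT_PRIMARY_ALPHA = 0.05

SCORE_COLUMNS = ["tf", "enhancer", "mode", "gene", "P2", "P4", "P5", "combined"]


class NoAnchorError(ValueError):
    """No usable (non-degenerate, significantly linked) anchor for a TF."""


@dataclass(frozen=True)
class AnchorCandidate:
    """One enhancer in one mode, with its primary-linkage p-value for a TF."""

    enhancer_id: str
    mode: str  # "continuous" | "binary"
    primary_pvalue: float

    def __post_init__(self) -> None:
        if self.mode not in ("continuous", "binary"):
            raise ValueError(f"unknown anchor mode {self.mode!r}")
        if not 0.0 <= self.primary_pvalue <= 1.0:
            raise ValueError("primary p-value outside [0, 1]")


def combined_posterior(p2, p4, p5):
    """Default combined causality score P = 1/2 (P2 P5 + P4)."""
    p2, p4, p5 = (np.asarray(p, dtype=float) for p in (p2, p4, p5))
    for p in (p2, p4, p5):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("posteriors must lie in [0, 1]")
    out = 0.5 * (p2 * p5 + p4)
    return float(out) if out.ndim == 0 else out


def traditional_posterior(p2, p3):
    """Baseline score P2 * P3: secondary linkage AND conditional independence."""
    p2, p3 = (np.asarray(p, dtype=float) for p in (p2, p3))
    for p in (p2, p3):
        if np.any((p < 0) | (p > 1)):
            raise ValueError("posteriors must lie in [0, 1]")
    out = p2 * p3
    return float(out) if out.ndim == 0 else out


def _encode_anchor(raw: np.ndarray, mode: str) -> np.ndarray:
    if mode == "continuous":
        return at.rank_normal_transform(raw)
    if mode == "binary":
        return at.encode_binary_anchor(raw)
    raise ValueError(f"unknown anchor mode {mode!r}")


def primary_linkage_pvalue(raw_anchor: np.ndarray, tf_norm: np.ndarray, mode: str) -> float:
    """p-value of the primary linkage test E -> A for one anchor encoding."""
    e = _encode_anchor(np.asarray(raw_anchor, dtype=float), mode)
    n = e.size
    rho = at.pair_correlation(e, tf_norm)
    return at.null_pvalue(at.llr_linkage(rho, n), n, test_id=1)


def build_anchor_candidates(
    enhancer_rows: pd.DataFrame, tf_expression: np.ndarray
) -> list[AnchorCandidate]:
    """Both encodings of every enhancer, with primary-linkage p-values.

    Degenerate encodings (all-zero / all-nonzero for binary; constant for
    continuous) are silently dropped, so an enhancer contributes at most two
    candidates.
    """
    tf_norm = at.rank_normal_transform(np.asarray(tf_expression, dtype=float))
    out = []
    for enh_id, row in enhancer_rows.iterrows():
        raw = row.to_numpy(dtype=float)
        for mode in ("continuous", "binary"):
            try:
                p = primary_linkage_pvalue(raw, tf_norm, mode)
            except (at.DegenerateVariableError, at.SingularCorrelationError):
                continue
            out.append(AnchorCandidate(str(enh_id), mode, p))
    return out


def select_anchor_adaptive(candidates: list[AnchorCandidate]) -> tuple[str, str]:
    """(enhancer, mode) with the smallest primary-linkage p-value.

    An exact p-value tie between modes is resolved in favour of the
    continuous encoding (it retains more information).
    """
    if not candidates:
        raise NoAnchorError("no usable anchor candidate")
    order = {"continuous": 0, "binary": 1}
    best = min(candidates, key=lambda c: (c.primary_pvalue, order[c.mode], c.enhancer_id))
    return best.enhancer_id, best.mode


def predict_targets(
    anchor_raw,
    tf_expression,
    targets_expression: pd.DataFrame,
    mode: str = "continuous",
    combination: str = "default",
) -> pd.DataFrame:
    """Score every candidate target gene B for one (anchor E, TF A) pair.

    Runs the secondary-linkage, conditional-independence, relevance and
    controlled tests for each B (the primary test involves only E and A),
    converts LLRs to p-values, pools each test's p-values across all B for
    empirical-Bayes posterior estimation, and emits the combined score.

    Returns a DataFrame indexed by gene with columns llr2..llr5, p2..p5,
    P2..P5 and ``combined``. ``targets_expression`` rows are candidate B
    genes on the (log) expression scale; the TF itself must already be
    excluded from it.
    """
    if combination not in ("default", "traditional"):
        raise ValueError(f"unknown combination {combination!r}")
    anchor_raw = np.asarray(anchor_raw, dtype=float)
    e = _encode_anchor(anchor_raw, mode)
    a = at.rank_normal_transform(np.asarray(tf_expression, dtype=float))
    n = e.size
    if targets_expression.shape[1] != n:
        raise ValueError("sample dimension mismatch between anchor and targets")

    bmat = at.rank_normal_transform(targets_expression.to_numpy(dtype=float), axis=1)
    rho_ea = at.pair_correlation(e, a)
    rho_eb = bmat @ e / n
    rho_ab = bmat @ a / n

    llr = {
        2: at.llr_linkage(rho_eb, n),
        3: at.llr_conditional_independence(rho_ea, rho_eb, rho_ab, n),
        4: at.llr_relevance(rho_ea, rho_eb, rho_ab, n),
        5: at.llr_controlled(rho_ea, rho_eb, rho_ab, n),
    }
    pval = {t: np.atleast_1d(at.null_pvalue(llr[t], n, t)) for t in llr}

    n_cand = targets_expression.shape[0]
    if n_cand < at.MIN_CANDIDATES_FOR_EB:
        warnings.warn(
            f"only {n_cand} candidate targets; posteriors fall back to 1 - p",
            stacklevel=2,
        )
    post = {t: at.posteriors_from_pvalues(pval[t], side="alt") for t in (2, 4, 5)}
    # test 3's *null* (conditional independence) is the supported model
    post[3] = at.posteriors_from_pvalues(pval[3], side="null")

    if combination == "default":
        score = combined_posterior(post[2], post[4], post[5])
    else:
        score = traditional_posterior(post[2], post[3])

    out = pd.DataFrame(index=targets_expression.index.astype(str))
    for t in (2, 3, 4, 5):
        out[f"llr{t}"] = np.atleast_1d(llr[t])
        out[f"p{t}"] = pval[t]
        out[f"P{t}"] = post[t]
    out["combined"] = np.atleast_1d(score)
    return out


def meta_enhancer(enhancer_rows: pd.DataFrame) -> np.ndarray:
    """Per-sample median across all of a TF's enhancers (a 'meta-enhancer')."""
    if enhancer_rows.shape[0] == 0:
        raise ValueError("no enhancer rows")
    return enhancer_rows.median(axis=0).to_numpy(dtype=float)


def consensus_targets_pca(binary_prediction_matrix: pd.DataFrame) -> pd.Series:
    """Gene loadings of the first PC of an enhancers x genes 0/1 matrix.

    The eigenvector sign is arbitrary, so the loading vector is flipped if
    needed to correlate non-negatively with the per-gene prediction means;
    the result is a consensus target score across enhancers.
    """
    from sklearn.decomposition import PCA

    mat = binary_prediction_matrix.to_numpy(dtype=float)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 enhancers and 2 genes")
    if np.ptp(mat) == 0:
        raise ValueError("constant prediction matrix has no principal component")
    centered = mat - mat.mean(axis=0)
    if np.allclose(centered, 0.0):
        # all enhancers agree: the consensus is the common (centered) pattern
        loadings = mat[0] - mat[0].mean()
        loadings = loadings / np.linalg.norm(loadings)
    else:
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(mat)
        loadings = pca.components_[0]
    col_means = mat.mean(axis=0)
    if np.dot(loadings, col_means - col_means.mean()) < 0:
        loadings = -loadings
    return pd.Series(loadings, index=binary_prediction_matrix.columns, name="consensus")


def target_set_jaccard_clustering(sets: list[TargetSet]):
    """Pairwise Jaccard similarity and average-linkage leaf order.

    Returns ``(similarity DataFrame, leaf-order list of labels)``; labels are
    ``tf_id`` (suffixed with provenance only when duplicated). Deterministic.
    """
    if len(sets) < 2:
        raise ValueError("need at least two target sets")
    labels = []
    seen: dict[str, int] = {}
    for s in sets:
        lbl = s.tf_id
        if lbl in seen:
            seen[lbl] += 1
            lbl = f"{lbl}.{seen[s.tf_id]}"
        else:
            seen[lbl] = 0
        labels.append(lbl)
    k = len(sets)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = sets[i].genes, sets[j].genes
            union = len(a | b)
            sim[i, j] = sim[j, i] = (len(a & b) / union) if union else 0.0
    dist = squareform(1.0 - sim, checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(link)
    sim_df = pd.DataFrame(sim, index=labels, columns=labels)
    return sim_df, [labels[i] for i in order]


def write_score_table(scores: pd.DataFrame, path) -> None:
    """Write the long-form score table with the stable column ordering."""
    scores.loc[:, SCORE_COLUMNS].to_csv(path, sep="\t", index=False)
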