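"""Stress-programme scoring and subtype assignment.

Cancer cells enter G0 arrest under different stimuli — spontaneously or in
response to contact inhibition, serum starvation, CDK4/6 inhibition or MEK
inhibition. Each programme is scored with the combined Z-score over its
dedicated 10-up/10-down signature. Bulk samples with a positive generic G0
score are assigned a stress subtype conservatively: the top-scoring
programme must exceed the cohort mean by one standard deviation of that
programme's score distribution and its per-gene z contributions must be
significantly higher than the pooled contributions of the other programmes
(Welch's t test); anything else is 'uncertain'. Single cells are instead
mapped onto labelled bulk reference profiles by k-nearest neighbours in PCA
space after batch adjustment, with a 2-of-3 vote needed for a call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import (
    STRESS_PROGRAMMES,
    UNCERTAIN,
    ExpressionMatrix,
    GeneSignature,
    StressSignatureSet,
    ValidationError,
)
from .scoring import batch_adjust, combined_zscore, signed_z_contributions

logger = logging.getLogger(__name__)

__all__ = [
    "StressScoreMatrix",
    "SubtypeCall",
    "ReferenceSet",
    "score_stress_programmes",
    "assign_bulk_subtype",
    "knn_project_classify",
]


@dataclass
class StressScoreMatrix:
    """Per-sample scores for the five stress programmes plus the generic
    G0 score, with the per-gene signed z contributions behind each score."""

    samples: list[str]
    programmes: tuple[str, ...]
    scores: np.ndarray  # samples x programmes
    generic_score: np.ndarray
    contributions: dict[str, pd.DataFrame]  # programme -> genes x samples

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.generic_score = np.asarray(self.generic_score, dtype=float)
        if self.scores.shape != (len(self.samples), len(self.programmes)):
            raise ValidationError("stress score matrix shape mismatch")
        if self.generic_score.shape != (len(self.samples),):
            raise ValidationError("generic score length mismatch")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.scores, index=self.samples, columns=list(self.programmes))
        frame["generic"] = self.generic_score
        return frame


@dataclass
class SubtypeCall:
    """One stress-subtype label per sample ('uncertain' when no programme
    passes the classification rule)."""

    samples: list[str]
    subtype: list[str]

    def __post_init__(self) -> None:
        if len(self.subtype) != len(self.samples):
            raise ValidationError("subtype length does not match samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.samples, "subtype": self.subtype})


@dataclass
class ReferenceSet:
    """Labelled bulk reference expression profiles, one programme label per
    reference sample."""

    expr: ExpressionMatrix
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != self.expr.n_samples:
            raise ValidationError("reference labels length does not match samples")


def score_stress_programmes(
    expr: ExpressionMatrix,
    sigs: StressSignatureSet,
    generic: GeneSignature,
) -> StressScoreMatrix:
    """Combined Z-score per stress programme and for the generic signature."""
    scores = np.empty((expr.n_samples, len(STRESS_PROGRAMMES)))
    contributions: dict[str, pd.DataFrame] = {}
    for k, (programme, sig) in enumerate(sigs.items()):
        if not expr.gene_index(sig.genes).size:
            raise ValidationError(
                f"no genes of stress programme {programme!r} present in the matrix"
            )
        sv = combined_zscore(expr, sig)
        scores[:, k] = sv.score
        contributions[programme] = signed_z_contributions(expr, sig)
    generic_sv = combined_zscore(expr, generic)
    return StressScoreMatrix(
        samples=list(expr.samples),
        programmes=STRESS_PROGRAMMES,
        scores=scores,
        generic_score=generic_sv.score,
        contributions=contributions,
    )


def assign_bulk_subtype(
    ssm: StressScoreMatrix,
    generic_threshold: float = 0.0,
    alpha: float = 0.05,
) -> SubtypeCall:
    """Assign bulk samples a stress-response subtype, conservatively.

    Samples whose generic G0 score does not exceed `generic_threshold` are
    'uncertain'. Otherwise the candidate is the argmax programme, accepted
    only if (a) its score exceeds the cohort mean + 1 SD of that programme's
    score distribution and (b) a two-sided Welch t test of the candidate's
    per-gene z contributions in that sample against the pooled contributions
    of the other four programmes gives p < `alpha` with a higher mean.
    """
    if len(ssm.samples) < 3:
        raise ValidationError("cohort of >=3 samples required (SD of score distribution)")
    if not ssm.contributions:
        raise ValidationError("per-gene contributions are required for the t-test rule")
    mean = ssm.scores.mean(axis=0)
    sd = ssm.scores.std(axis=0, ddof=1)
    calls: list[str] = []
    for j, sample in enumerate(ssm.samples):
        if ssm.generic_score[j] <= generic_threshold:
            calls.append(UNCERTAIN)
            continue
        k = int(np.argmax(ssm.scores[j]))
        programme = ssm.programmes[k]
        if ssm.scores[j, k] <= mean[k] + sd[k]:
            calls.append(UNCERTAIN)
            continue
        cand = ssm.contributions[programme][sample].to_numpy()
        others = np.concatenate(
            [ssm.contributions[p][sample].to_numpy() for p in ssm.programmes if p != programme]
        )
        if cand.size < 2 or others.size < 2:
            calls.append(UNCERTAIN)
            continue
        t, p = stats.ttest_ind(cand, others, equal_var=False)
        if p < alpha and cand.mean() > others.mean():
            calls.append(programme)
        else:
            calls.append(UNCERTAIN)
    return SubtypeCall(samples=list(ssm.samples), subtype=calls)


def knn_project_classify(
    query: ExpressionMatrix,
    ref: ReferenceSet,
    k: int = 3,
    min_votes: int = 2,
    n_pcs: int = 10,
) -> SubtypeCall:
    """Classify query cells/samples by kNN mapping onto labelled references.

    Steps: restrict both matrices to shared genes; remove the study batch
    effect between query and reference (per-batch location-scale
    standardisation); fit PCA on the combined matrix; for every query point
    take the `k` nearest reference points (Euclidean distance in PC space)
    and assign any label holding at least `min_votes` of the k, else
    'uncertain'. Distance ties at the k-th neighbour break by reference
    sample ID order.
    """
    shared = [g for g in query.genes if g in set(ref.expr.genes)]
    if not shared:
        raise ValidationError("query and reference share no genes")
    if ref.expr.n_samples < k:
        raise ValidationError(f"need >=k={k} reference points, got {ref.expr.n_samples}")
    q = query.subset_genes(shared)
    r = ref.expr.subset_genes(shared)
    combined = ExpressionMatrix(
        genes=shared,
        samples=[f"q::{s}" for s in q.samples] + [f"r::{s}" for s in r.samples],
        values=np.hstack([q.values, r.values]),
        log_scale=query.log_scale,
    )
    batches = ["query"] * q.n_samples + ["ref"] * r.n_samples
    adjusted = batch_adjust(combined, batches, rescale_to_pooled=False)

    x = adjusted.values.T  # samples x genes
    max_rank = min(x.shape[0], x.shape[1])
    if n_pcs > max_rank:
        logger.warning("n_pcs=%d exceeds matrix rank; clipped to %d", n_pcs, max_rank)
        n_pcs = max_rank
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(x)
    q_pcs = pcs[: q.n_samples]
    r_pcs = pcs[q.n_samples:]

    # deterministic tie-break: pre-sort reference points by sample ID
    ref_order = np.argsort(np.asarray(r.samples, dtype=object))
    r_pcs = r_pcs[ref_order]
    ref_labels = [ref.labels[i] for i in ref_order]

    calls: list[str] = []
    for row in q_pcs:
        d = np.linalg.norm(r_pcs - row[None, :], axis=1)
        nearest = np.argsort(d, kind="stable")[:k]
        votes: dict[str, int] = {}
        for i in nearest:
            votes[ref_labels[i]] = votes.get(ref_labels[i], 0) + 1
        label, count = max(votes.items(), key=lambda kv: kv[1])
        calls.append(label if count >= min_votes else UNCERTAIN)
    return SubtypeCall(samples=list(query.samples), subtype=calls)
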