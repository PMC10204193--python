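"""Per-sample and per-cell G0-arrest scoring and classification.

The selected scoring method is the combined Z-score: standardise each gene
across samples, sum the z-values of the up-regulated signature genes divided
by the square root of their number, do the same for the down-regulated
genes, and subtract the down score from the up score. Higher scores mean a
stronger G0-arrest signal, everywhere in this package.

Also provided: the mean-scaled score ``G0m = (mean(G_U) - mean(G_D)) /
mean(G_H)`` over up, down and housekeeping gene sets; a simple normalised
rank-based comparator; tumour-purity adjustment of bulk expression; state
calling and proportion summaries; ROC-AUC evaluation; and two-group
high/low partitioning by k-means after batch adjustment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .containers import (
    G0,
    PROLIFERATING,
    ExpressionMatrix,
    GeneSignature,
    HousekeepingSet,
    PurityVector,
    ScoreVector,
    StateLabels,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "zscore_transform",
    "combined_zscore",
    "mean_scaled_score",
    "rank_score",
    "purity_adjust",
    "call_states",
    "proportion_arrested",
    "evaluate_auc",
    "batch_adjust",
    "kmeans_high_low",
]


# ---------------------------------------------------------------------------
# Standardisation and scoring
# ---------------------------------------------------------------------------

def zscore_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise each gene across samples to mean 0, SD 1 (n-1 SD).

    Zero-variance genes cannot be standardised; their rows are set to 0 and
    a warning lists them.
    """
    if expr.n_samples < 2:
        raise ValidationError(
            "cohort-level z-scoring is undefined for a single sample; "
            "provide a matrix with >=2 samples"
        )
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    zero_var = (sd[:, 0] == 0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (expr.values - mean) / sd_safe
    z[zero_var, :] = 0.0
    if zero_var.any():
        flagged = [g for g, zv in zip(expr.genes, zero_var) if zv]
        logger.warning("%d zero-variance genes set to 0: %s", len(flagged), flagged[:10])
    return ExpressionMatrix(
        genes=list(expr.genes), samples=list(expr.samples), values=z,
        log_scale=expr.log_scale,
    )


def _direction_z(expr: ExpressionMatrix, genes: list[str]) -> tuple[np.ndarray, np.ndarray, list[str], int]:
    """Signed per-gene z contributions for one signature direction.

    Returns (z matrix over usable genes, direction score per sample, usable
    gene names, number of signature genes present in the matrix). Usable
    genes are those present with nonzero variance; the direction score is
    ``sum(z) / sqrt(n_usable)``.
    """
    idx = expr.gene_index(genes)
    n_present = idx.size
    if n_present == 0:
        return np.empty((0, expr.n_samples)), np.zeros(expr.n_samples), [], 0
    sub = expr.values[idx, :]
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    usable = sd[:, 0] > 0
    names = [expr.genes[i] for i, u in zip(idx, usable) if u]
    z = (sub[usable] - mean[usable]) / sd[usable]
    n_usable = int(usable.sum())
    if n_usable == 0:
        return z, np.zeros(expr.n_samples), names, n_present
    score = z.sum(axis=0) / np.sqrt(n_usable)
    return z, score, names, n_present


def combined_zscore(expr: ExpressionMatrix, sig: GeneSignature) -> ScoreVector:
    """Combined Z-score of G0 arrest: up-set z sum minus down-set z sum.

    Per sample j: ``Z_up(j) = sum_i z_ij / sqrt(n_up)`` over up genes present
    in the matrix (analogously for the down set) and the final score is
    ``Z_up - Z_down``. Signature genes missing from the matrix (dropout) are
    silently excluded; zero-variance genes contribute 0 and are excluded
    from the square-root normaliser.
    """
    if expr.n_samples < 2:
        raise ValidationError("combined Z-score needs >=2 samples to standardise genes")
    _, z_up, _, n_up = _direction_z(expr, sig.up)
    _, z_down, _, n_down = _direction_z(expr, sig.down)
    if n_up == 0 and n_down == 0:
        raise ValidationError(
            f"no genes of signature '{sig.name}' present in the expression matrix"
        )
    if n_up == 0 or n_down == 0:
        missing = "up" if n_up == 0 else "down"
        logger.warning(
            "signature '%s': no %s-regulated genes present; score uses the "
            "other direction only", sig.name, missing,
        )
    return ScoreVector(
        samples=list(expr.samples),
        score=z_up - z_down,
        method="combined_zscore",
        n_up_used=n_up,
        n_down_used=n_down,
    )


def signed_z_contributions(expr: ExpressionMatrix, sig: GeneSignature) -> pd.DataFrame:
    """Per-gene signed z contributions (genes x samples).

    Up genes contribute ``+z``, down genes ``-z``, so that
    ``score = sum(contributions) / sqrt(n)`` separately per direction is the
    combined Z-score. Used by the stress-subtype t-test rule.
    """
    z_up, _, up_names, _ = _direction_z(expr, sig.up)
    z_down, _, down_names, _ = _direction_z(expr, sig.down)
    rows = np.vstack([z_up, -z_down]) if (z_up.size or z_down.size) else np.empty((0, expr.n_samples))
    return pd.DataFrame(rows, index=up_names + down_names, columns=expr.samples)


def mean_scaled_score(
    expr: ExpressionMatrix, sig: GeneSignature, hk: HousekeepingSet
) -> ScoreVector:
    """Mean-scaled G0 score: ``(mean(G_U) - mean(G_D)) / mean(G_H)``.

    Means are taken per sample over the genes of each set present in the
    matrix. Housekeeping genes overlapping the signature are excluded from
    the housekeeping mean.
    """
    up_idx = expr.gene_index(sig.up)
    down_idx = expr.gene_index(sig.down)
    hk_genes = [g for g in hk.genes if g not in set(sig.genes)]
    hk_idx = expr.gene_index(hk_genes)
    if up_idx.size == 0 or down_idx.size == 0:
        raise ValidationError("mean-scaled score needs >=1 up and >=1 down gene present")
    if hk_idx.size == 0:
        raise ValidationError("no housekeeping genes present in the expression matrix")
    mean_up = expr.values[up_idx, :].mean(axis=0)
    mean_down = expr.values[down_idx, :].mean(axis=0)
    mean_hk = expr.values[hk_idx, :].mean(axis=0)
    zero = np.isclose(mean_hk, 0.0)
    if zero.any():
        bad = [s for s, z in zip(expr.samples, zero) if z]
        raise ValidationError(f"housekeeping mean expression is 0 for samples: {bad[:10]}")
    return ScoreVector(
        samples=list(expr.samples),
        score=(mean_up - mean_down) / mean_hk,
        method="mean_scaled",
        n_up_used=int(up_idx.size),
        n_down_used=int(down_idx.size),
    )


def rank_score(expr: ExpressionMatrix, sig: GeneSignature) -> ScoreVector:
    """Normalised-rank comparator score.

    Per sample, all genes are ranked ascending with mid-ranks for ties and
    ranks are normalised to [0, 1] via ``(rank - 1) / (N - 1)``; the score
    is the mean normalised rank of up genes minus that of down genes.
    """
    up_idx = expr.gene_index(sig.up)
    down_idx = expr.gene_index(sig.down)
    if up_idx.size == 0 and down_idx.size == 0:
        raise ValidationError(
            f"no genes of signature '{sig.name}' present in the expression matrix"
        )
    n = expr.n_genes
    if n < 2:
        raise ValidationError("rank score needs >=2 genes in the matrix")
    ranks = np.apply_along_axis(stats.rankdata, 0, expr.values)
    norm = (ranks - 1.0) / (n - 1.0)
    score = np.zeros(expr.n_samples)
    if up_idx.size:
        score += norm[up_idx, :].mean(axis=0)
    if down_idx.size:
        score -= norm[down_idx, :].mean(axis=0)
    return ScoreVector(
        samples=list(expr.samples),
        score=score,
        method="rank",
        n_up_used=int(up_idx.size),
        n_down_used=int(down_idx.size),
    )


# ---------------------------------------------------------------------------
# Purity adjustment
# ---------------------------------------------------------------------------

def purity_adjust(
    expr: ExpressionMatrix,
    purity: PurityVector,
    min_purity: float = 0.30,
    mode: str = "divide",
) -> ExpressionMatrix:
    """Scale bulk expression by tumour purity and drop impure samples.

    Samples with purity below `min_purity` (default 30%) are removed. The
    remaining samples' values are divided by purity on the linear scale;
    when the matrix is on log2 scale the values are exponentiated, divided
    and re-logged (equivalently, ``log2(purity)`` is subtracted).
    `mode='none'` only applies the purity cutoff without rescaling.
    """
    if not (0 < min_purity <= 1):
        raise ValidationError("min_purity must lie in (0, 1]")
    if mode not in ("divide", "none"):
        raise ValidationError(f"unknown purity mode {mode!r}")
    pmap = dict(zip(purity.samples, purity.purity))
    missing = [s for s in expr.samples if s not in pmap]
    if missing:
        raise ValidationError(f"purity missing for samples: {missing[:10]}")
    keep = [s for s in expr.samples if pmap[s] >= min_purity]
    dropped = expr.n_samples - len(keep)
    if dropped:
        logger.info("purity filter removed %d of %d samples", dropped, expr.n_samples)
    if not keep:
        raise ValidationError("all samples fall below the purity cutoff")
    out = expr.subset_samples(keep)
    if mode == "none":
        return out
    p = np.array([pmap[s] for s in keep])
    if np.any(p == 0):
        raise ValidationError("cannot divide by purity 0")
    if out.log_scale:
        values = out.values - np.log2(p)[None, :]
    else:
        values = out.values / p[None, :]
    return ExpressionMatrix(
        genes=list(out.genes), samples=keep, values=values, log_scale=out.log_scale
    )


# ---------------------------------------------------------------------------
# State calling and evaluation
# ---------------------------------------------------------------------------

def call_states(
    scores: ScoreVector,
    threshold: float = 0.0,
    group: list[str] | None = None,
) -> StateLabels:
    """Label each sample G0-arrested iff its score strictly exceeds
    `threshold` (default 0 for combined Z-scores)."""
    states = [G0 if s > threshold else PROLIFERATING for s in scores.score]
    return StateLabels(samples=list(scores.samples), states=states, group=group)


def proportion_arrested(labels: StateLabels) -> pd.DataFrame:
    """Per-group G0-arrested fractions.

    Returns a frame with columns ``group``, ``fraction_G0``, ``n``. Without
    explicit groups a single implicit group 'all' is reported.
    """
    frame = labels.to_frame()
    if "group" not in frame.columns:
        frame["group"] = "all"
    rows = []
    for grp, sub in frame.groupby("group", sort=True):
        if len(sub) == 0:  # pragma: no cover - groupby never yields empties
            logger.warning("empty group %r omitted", grp)
            continue
        rows.append(
            {"group": grp, "fraction_G0": float((sub["state"] == G0).mean()), "n": len(sub)}
        )
    return pd.DataFrame(rows, columns=["group", "fraction_G0", "n"])


def evaluate_auc(scores: ScoreVector, truth: StateLabels) -> float:
    """ROC AUC of the score against known G0/proliferating labels.

    Computed via the rank (Mann-Whitney U) formulation with mid-rank tie
    correction; G0 is the positive class and higher scores indicate G0.
    """
    tmap = truth.as_mapping()
    missing = [s for s in scores.samples if s not in tmap]
    if missing:
        raise ValidationError(f"truth labels missing for samples: {missing[:10]}")
    y = np.array([tmap[s] == G0 for s in scores.samples])
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: truth labels contain a single class")
    ranks = stats.rankdata(scores.score)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Batch adjustment and k-means high/low partitioning
# ---------------------------------------------------------------------------

def batch_adjust(
    expr: ExpressionMatrix, batch: list[str], rescale_to_pooled: bool = True
) -> ExpressionMatrix:
    """Remove batch (e.g. tissue or study) effects by per-batch location-scale
    standardisation of each gene.

    Each gene is centred and variance-scaled within every batch; with
    `rescale_to_pooled` the standardised values are mapped back onto the
    gene's pooled across-batch mean/SD so the output stays on the expression
    scale, otherwise per-batch z-scores are returned (exactly invariant to
    any batch-wide gene-wise affine transform, the right form for distance-
    based classification). This is a deterministic, shrinkage-free
    counterpart of ComBat adequate for location/scale batch structure.
    """
    if len(batch) != expr.n_samples:
        raise ValidationError("batch labels length does not match samples")
    batch_arr = np.asarray(batch)
    values = expr.values.copy()
    pooled_mean = values.mean(axis=1, keepdims=True)
    pooled_sd = values.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(values)
    for b in np.unique(batch_arr):
        cols = batch_arr == b
        if cols.sum() < 2:
            raise ValidationError(f"batch {b!r} has fewer than 2 samples")
        sub = values[:, cols]
        m = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        out[:, cols] = (sub - m) / sd
    if rescale_to_pooled:
        out = out * np.where(pooled_sd == 0, 1.0, pooled_sd) + pooled_mean
    return ExpressionMatrix(
        genes=list(expr.genes), samples=list(expr.samples), values=out,
        log_scale=expr.log_scale,
    )


def kmeans_high_low(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    batch: list[str] | None = None,
    seed: int = 0,
    n_init: int = 25,
) -> StateLabels:
    """Partition samples into 'high' / 'low' G0-arrest groups.

    After batch adjustment (when `batch` is given), k-means with k=2 is run
    on the signature-gene submatrix; the cluster with the higher mean
    combined Z-score is labelled 'high'.
    """
    if expr.n_samples < 2:
        raise ValidationError("k-means partitioning needs >=2 samples")
    adj = batch_adjust(expr, batch) if batch is not None else expr
    sub = adj.subset_genes(sig.genes)
    if sub.n_genes == 0:
        raise ValidationError("no signature genes present for k-means partitioning")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed, tol=1e-6)
    assign = km.fit_predict(sub.values.T)
    if len(np.unique(assign)) < 2:
        raise ValidationError(
            "k-means collapsed to a single cluster; the cohort may be degenerate"
        )
    score = combined_zscore(adj, sig).score
    mean0 = score[assign == 0].mean()
    mean1 = score[assign == 1].mean()
    high_cluster = 0 if mean0 >= mean1 else 1
    states = ["high" if a == high_cluster else "low" for a in assign]
    return StateLabels(samples=list(expr.samples), states=states)
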