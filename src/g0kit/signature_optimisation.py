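"""Machine-learned reduction of the G0 signature for sparse single-cell data.

Single-cell data drop out genes; a smaller signature of highly informative
genes scores arrest more robustly there. The reduction runs in three steps:

1. *Per-gene importance.* On each training dataset (cells with known
   arrested/cycling states), random forests predicting the state from the
   signature genes are trained repeatedly; per-gene Gini importances are
   averaged over repetitions and min-max normalised to [0, 1] per dataset.
2. *Candidate subsets.* Sweeping a threshold from 0 to 1, a gene enters the
   candidate subset at threshold t if its normalised importance exceeds t
   in at least one training dataset.
3. *External validation.* Each candidate subset is scored with the combined
   Z-score on a validation cohort and correlated with experimental arrest
   measurements (e.g. phospho-Rb and EdU staining fractions); among subsets
   passing a significance gate on the mean correlation, the one with the
   highest correlation against the designated primary assay wins (ties go
   to the smaller subset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .containers import ExpressionMatrix, GeneSignature, StateLabels, ValidationError
from .scoring import combined_zscore

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceTable",
    "SubsetCandidate",
    "gini_importance",
    "threshold_sweep",
    "validate_subsets",
    "optimise_signature",
]


@dataclass
class ImportanceTable:
    """Min-max-normalised per-gene random-forest importances, one column
    per training dataset."""

    table: pd.DataFrame  # genes x datasets, values in [0, 1]

    def __post_init__(self) -> None:
        vals = self.table.to_numpy()
        if np.any((vals < 0) | (vals > 1)):
            raise ValidationError("normalised importances must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.table.index]


@dataclass
class SubsetCandidate:
    """A candidate reduced signature produced at one sweep threshold."""

    threshold: float
    genes: list[str]
    validation_corr: dict[str, float] = field(default_factory=dict)
    p: float = float("nan")


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi == lo:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def gini_importance(
    datasets: list[tuple[ExpressionMatrix, StateLabels]],
    sig: GeneSignature,
    n_rep: int = 100,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceTable:
    """Averaged, normalised random-forest Gini importances per gene.

    Per training dataset, `n_rep` seeded random forests are trained to
    predict the cell state from the signature-gene expression; per-gene
    Gini (impurity-decrease) importances are averaged across repetitions,
    then min-max normalised to [0, 1] across genes within the dataset.
    Genes absent from a dataset receive importance 0 there.
    """
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, pd.Series] = {}
    for d, (expr, labels) in enumerate(datasets):
        name = f"dataset_{d}"
        lmap = labels.as_mapping()
        y = np.array([lmap[s] for s in expr.samples])
        if len(np.unique(y)) < 2:
            raise ValidationError(f"{name}: both cell states must be present")
        sub = expr.subset_genes(sig.genes)
        if sub.n_genes == 0:
            raise ValidationError(f"{name}: no signature genes present")
        x = sub.values.T
        acc = np.zeros(sub.n_genes)
        for _ in range(n_rep):
            rf = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1))
            )
            rf.fit(x, y)
            acc += rf.feature_importances_
        mean_imp = pd.Series(_minmax(acc / n_rep), index=sub.genes)
        cols[name] = mean_imp.reindex(sig.genes, fill_value=0.0)
    return ImportanceTable(table=pd.DataFrame(cols, index=sig.genes))


def threshold_sweep(
    imp: ImportanceTable,
    thresholds: np.ndarray | None = None,
) -> list[SubsetCandidate]:
    """Candidate subsets from a gradually increasing importance threshold.

    At threshold t a gene qualifies if its importance exceeds t in at least
    one dataset. Thresholds yielding a subset already produced at a smaller
    threshold are collapsed (the smallest threshold is kept).
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0 + 1e-9, 0.01)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValidationError("threshold grid is empty")
    vals = imp.table.to_numpy()
    genes = np.asarray(imp.genes, dtype=object)
    seen: set[frozenset[str]] = set()
    out: list[SubsetCandidate] = []
    for t in thresholds:
        mask = (vals > t).any(axis=1)
        subset = [str(g) for g in genes[mask]]
        key = frozenset(subset)
        if key in seen or not subset:
            continue
        seen.add(key)
        out.append(SubsetCandidate(threshold=float(t), genes=subset))
    return out


def _corr_p(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the t transform."""
    if n < 3 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else 1.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def validate_subsets(
    cands: list[SubsetCandidate],
    val_expr: ExpressionMatrix,
    measurements: dict[str, np.ndarray],
    sig: GeneSignature,
    primary_assay: str | None = None,
    alpha: float = 0.05,
) -> SubsetCandidate:
    """Select the best candidate subset against experimental measurements.

    Per candidate: score the validation cohort with the combined Z-score of
    the candidate genes (directions inherited from the full signature) and
    correlate (Pearson) with each assay's measurements. Candidates whose
    *mean* assay correlation is significant (p < `alpha` via the t
    transform) qualify; among them the candidate maximising the primary
    assay's correlation wins, ties resolved towards the smaller subset. If
    no candidate clears the gate, the best by primary correlation is
    returned with a warning.
    """
    if not cands:
        raise ValidationError("no candidate subsets to validate")
    if not measurements:
        raise ValidationError("at least one measurement vector is required")
    if primary_assay is None:
        primary_assay = next(iter(measurements))
    if primary_assay not in measurements:
        raise ValidationError(f"unknown primary assay {primary_assay!r}")
    n = val_expr.n_samples
    for assay, m in measurements.items():
        if len(m) != n:
            raise ValidationError(f"measurement {assay!r} length does not match samples")

    evaluated: list[SubsetCandidate] = []
    for cand in cands:
        subset_sig = sig.restrict(cand.genes, name=f"subset_t{cand.threshold:.2f}")
        if not val_expr.gene_index(subset_sig.genes).size:
            logger.warning(
                "candidate at threshold %.2f has no genes in the validation matrix; skipped",
                cand.threshold,
            )
            continue
        score = combined_zscore(val_expr, subset_sig).score
        corrs = {
            assay: float(stats.pearsonr(score, np.asarray(m, dtype=float))[0])
            for assay, m in measurements.items()
        }
        mean_r = float(np.mean(list(corrs.values())))
        evaluated.append(
            SubsetCandidate(
                threshold=cand.threshold,
                genes=list(cand.genes),
                validation_corr=corrs,
                p=_corr_p(mean_r, n),
            )
        )
    if not evaluated:
        raise ValidationError("no candidate subset could be scored on the validation data")

    passing = [c for c in evaluated if c.p < alpha]
    pool = passing if passing else evaluated
    if not passing:
        logger.warning("no candidate cleared the significance gate; returning best overall")
    best = max(pool, key=lambda c: (c.validation_corr[primary_assay], -len(c.genes)))
    return best


def optimise_signature(
    datasets: list[tuple[ExpressionMatrix, StateLabels]],
    sig: GeneSignature,
    val_expr: ExpressionMatrix,
    measurements: dict[str, np.ndarray],
    n_rep: int = 100,
    seed: int = 0,
    n_trees: int = 500,
    thresholds: np.ndarray | None = None,
    primary_assay: str | None = None,
    alpha: float = 0.05,
) -> tuple[GeneSignature, SubsetCandidate, ImportanceTable]:
    """End-to-end signature reduction: importance, sweep, validation."""
    imp = gini_importance(datasets, sig, n_rep=n_rep, seed=seed, n_trees=n_trees)
    cands = threshold_sweep(imp, thresholds)
    best = validate_subsets(
        cands, val_expr, measurements, sig, primary_assay=primary_assay, alpha=alpha
    )
    reduced = sig.restrict(best.genes, name=f"{sig.name}_reduced")
    return reduced, best, imp
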