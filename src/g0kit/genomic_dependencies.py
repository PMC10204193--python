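"""Genomic determinants of G0 arrest.

Links the transcriptomic G0-arrest score to genomic features (driver-gene
mutation/amplification/deletion indicators, mutation rate, ploidy,
aneuploidy, mutational-signature exposures, tissue) through:

* Fisher's-exact driver prioritisation (enrichment/depletion of events in
  high- vs low-arrest samples, BH-corrected);
* an ensemble elastic net — the model is refit on many random 90%
  subsamples of the training cohort and only features selected (nonzero)
  in *every* iteration form the consensus;
* a consensus linear model whose coefficients are the per-iteration
  averages, with exact per-sample Shapley attributions
  ``phi_jk = coef_k * (x_jk - mean_k)``;
* a tissue-specific classifier: top-k features by one-way ANOVA F statistic
  feeding a random forest, accuracy averaged over random stratified splits.

Samples with fewer than 50 mutations are excluded from the regression
(mutational-signature exposures are unreliable below that), and the
mutation-rate covariate is ``log10(n_mutations / 38 Mb)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import StratifiedShuffleSplit
from statsmodels.stats.multitest import multipletests

from .containers import G0, ScoreVector, StateLabels, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicFeatureMatrix",
    "EnsembleResult",
    "LinearConsensusModel",
    "mutation_rate",
    "prioritise_drivers",
    "ensemble_elastic_net",
    "consensus_linear_model",
    "linear_shap",
    "anova_rf_tissue_model",
]

#: Exome capture length in megabases used for mutation-rate normalisation.
EXOME_CAPTURE_MB = 38.0

#: Coefficients with absolute value at or below this are treated as zero.
COEF_ZERO_TOL = 1e-8

#: Default l1-ratio (mixing) grid searched by internal cross-validation.
L1_RATIO_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


@dataclass
class GenomicFeatureMatrix:
    """Samples x genomic features, with a per-feature type schema.

    ``schema`` maps feature name to 'binary', 'continuous' or 'categorical'.
    Binary columns must contain only 0/1; categorical columns (e.g. tissue)
    are one-hot encoded at model time. ``n_mutations`` carries the total
    somatic mutation count per sample for the >=50-mutation filter.
    """

    features: pd.DataFrame  # samples in rows
    schema: dict[str, str]
    n_mutations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        if self.features.columns.has_duplicates:
            raise ValidationError("duplicate feature names")
        unknown = [c for c in self.features.columns if c not in self.schema]
        if unknown:
            raise ValidationError(f"features missing from schema: {unknown[:10]}")
        bad_types = {t for t in self.schema.values()} - {"binary", "continuous", "categorical"}
        if bad_types:
            raise ValidationError(f"unknown feature types in schema: {sorted(bad_types)}")
        if self.features.isna().any().any():
            raise ValidationError("feature matrix contains missing values")
        for c in self.features.columns:
            if self.schema[c] == "binary":
                vals = set(pd.unique(self.features[c]))
                if not vals <= {0, 1, 0.0, 1.0, True, False}:
                    raise ValidationError(f"binary feature {c!r} has non-0/1 values")
        if self.n_mutations is not None:
            self.n_mutations = np.asarray(self.n_mutations)
            if self.n_mutations.shape != (len(self.features),):
                raise ValidationError("n_mutations length does not match samples")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.features.index]

    def binary_features(self) -> list[str]:
        return [c for c in self.features.columns if self.schema[c] == "binary"]

    def design_matrix(self, standardise_continuous: bool = True) -> pd.DataFrame:
        """Numeric design matrix: binary kept 0/1, continuous optionally
        standardised, categoricals one-hot encoded."""
        blocks: list[pd.DataFrame] = []
        for c in self.features.columns:
            kind = self.schema[c]
            if kind == "categorical":
                onehot = pd.get_dummies(self.features[c], prefix=c, dtype=float)
                blocks.append(onehot)
            elif kind == "continuous" and standardise_continuous:
                col = self.features[c].astype(float)
                sd = col.std(ddof=1)
                blocks.append(((col - col.mean()) / (sd if sd > 0 else 1.0)).to_frame())
            else:
                blocks.append(self.features[c].astype(float).to_frame())
        return pd.concat(blocks, axis=1)


@dataclass
class EnsembleResult:
    """Per-iteration elastic-net selections and the all-iterations consensus."""

    iterations: list[tuple[frozenset[str], dict[str, float]]]
    consensus_features: list[str]
    mean_coefficients: dict[str, float]
    n_iter: int

    def __post_init__(self) -> None:
        if set(self.mean_coefficients) != set(self.consensus_features):
            raise ValidationError("mean coefficients must cover exactly the consensus features")


@dataclass
class LinearConsensusModel:
    """Linear model with averaged ensemble coefficients.

    ``feature_means`` are training-set means, stored for exact linear
    Shapley attribution.
    """

    intercept: float
    coefficients: dict[str, float]
    feature_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.feature_means):
            raise ValidationError("coefficient and feature-mean vectors are misaligned")

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValidationError(f"features missing from input: {missing[:10]}")
        coefs = np.array([self.coefficients[f] for f in self.feature_names])
        return self.intercept + X[self.feature_names].to_numpy(dtype=float) @ coefs


def mutation_rate(
    n_mutations: int | np.ndarray,
    exome_mb: float = EXOME_CAPTURE_MB,
    floor: float | None = None,
) -> float | np.ndarray:
    """Log10 mutation rate: ``log10(n_mutations / exome_mb)``.

    Zero mutation counts are an error unless a pseudo-count `floor` is
    configured (counts below the floor are raised to it).
    """
    n = np.asarray(n_mutations, dtype=float)
    if floor is not None:
        n = np.maximum(n, floor)
    if np.any(n <= 0):
        raise ValidationError(
            "mutation rate undefined for 0 mutations; configure a pseudo-count floor"
        )
    out = np.log10(n / exome_mb)
    return float(out) if np.isscalar(n_mutations) or np.ndim(n_mutations) == 0 else out


def prioritise_drivers(
    events: GenomicFeatureMatrix,
    groups: StateLabels,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Test binary genomic events for enrichment/depletion in high-G0 samples.

    Per binary feature a 2x2 Fisher's exact test (event x group) is run and
    Benjamini-Hochberg q-values computed; features with q < `alpha_fdr` are
    flagged. 'high' group = samples labelled G0 or 'high'.
    """
    gmap = groups.as_mapping()
    missing = [s for s in events.samples if s not in gmap]
    if missing:
        raise ValidationError(f"group labels missing for samples: {missing[:10]}")
    is_high = np.array([gmap[s] in (G0, "high") for s in events.samples])
    if is_high.all() or not is_high.any():
        raise ValidationError("both high- and low-G0 groups must be non-empty")
    rows = []
    for feat in events.binary_features():
        x = events.features[feat].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            logger.warning("feature %r constant across samples; skipped", feat)
            continue
        a = int(np.sum((x == 1) & is_high))   # event in high
        b = int(np.sum((x == 1) & ~is_high))  # event in low
        c = int(np.sum((x == 0) & is_high))
        d = int(np.sum((x == 0) & ~is_high))
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({"feature": feat, "odds_ratio": odds, "p": p,
                     "direction": "enriched" if odds > 1 else "depleted"})
    if not rows:
        return pd.DataFrame(columns=["feature", "odds_ratio", "p", "q", "direction", "significant"])
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["q"] < alpha_fdr
    return table[["feature", "odds_ratio", "p", "q", "direction", "significant"]]


# ---------------------------------------------------------------------------
# Ensemble elastic net
# ---------------------------------------------------------------------------

def ensemble_elastic_net(
    X: GenomicFeatureMatrix,
    y: ScoreVector,
    n_iter: int = 1000,
    subsample_frac: float = 0.9,
    min_mutations: int = 50,
    seed: int = 0,
    l1_ratios: tuple[float, ...] = L1_RATIO_GRID,
    cv: int = 10,
    n_alphas: int = 50,
    alpha_rule: str = "1se",
    tune_per_iteration: bool = False,
) -> EnsembleResult:
    """Ensemble elastic-net feature selection with all-iterations consensus.

    Samples with fewer than `min_mutations` mutations are removed, then the
    elastic net is fit `n_iter` times, each on a random `subsample_frac`
    fraction of samples drawn without replacement. The penalty strength and
    l1/l2 mixing are chosen by internal cross-validation (by default once,
    on the full filtered training set; set `tune_per_iteration` to re-tune
    inside every subsample). `alpha_rule` picks either the minimum-CV-error
    penalty ('min') or the strongest penalty within one standard error of
    the minimum ('1se', default — the usual choice when the goal is support
    recovery rather than prediction). Features with nonzero coefficients in
    *all* iterations form the consensus; their coefficients are averaged
    across iterations.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if not (0 < subsample_frac <= 1):
        raise ValidationError("subsample_frac must lie in (0, 1]")
    ymap = dict(zip(y.samples, y.score))
    missing = [s for s in X.samples if s not in ymap]
    if missing:
        raise ValidationError(f"scores missing for samples: {missing[:10]}")

    design = X.design_matrix()
    keep = np.ones(len(design), dtype=bool)
    if X.n_mutations is not None:
        keep = X.n_mutations >= min_mutations
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d samples with < %d mutations", dropped, min_mutations)
    design = design.loc[keep]
    yv = np.array([ymap[s] for s, k in zip(X.samples, keep) if k])
    n = len(design)
    if n < 3:
        raise ValidationError("too few samples after the mutation filter")

    if alpha_rule not in ("min", "1se"):
        raise ValidationError(f"unknown alpha rule {alpha_rule!r}")
    rng = np.random.default_rng(seed)
    feature_names = list(design.columns)
    Xa = design.to_numpy(dtype=float)

    def _tune(x: np.ndarray, target: np.ndarray) -> tuple[float, float]:
        tuner = ElasticNetCV(
            l1_ratio=list(l1_ratios), alphas=n_alphas, cv=cv,
            random_state=int(rng.integers(2**31 - 1)), max_iter=10000,
        ).fit(x, target)
        if alpha_rule == "min":
            return float(tuner.alpha_), float(tuner.l1_ratio_)
        # 1-SE rule over the full (l1_ratio, alpha) grid: strongest penalty
        # whose mean CV error is within one SE of the minimum
        mse = tuner.mse_path_  # (n_l1, n_alpha, n_folds)
        mean = mse.mean(axis=2)
        se = mse.std(axis=2, ddof=1) / np.sqrt(mse.shape[2])
        i_min = np.unravel_index(np.argmin(mean), mean.shape)
        thresh = mean[i_min] + se[i_min]
        best: tuple[tuple[float, float], tuple[float, float]] | None = None
        for i, l1 in enumerate(l1_ratios):
            for j, a in enumerate(tuner.alphas_[i]):
                if mean[i, j] <= thresh:
                    key = (float(a), float(l1))
                    if best is None or key > best[0]:
                        best = (key, (float(l1), float(a)))
        assert best is not None
        l1_sel, a_sel = best[1]
        return a_sel, l1_sel

    fixed_params: tuple[float, float] | None = None
    if not tune_per_iteration:
        fixed_params = _tune(Xa, yv)

    n_sub = int(np.floor(subsample_frac * n))
    iterations: list[tuple[frozenset[str], dict[str, float]]] = []
    for _ in range(n_iter):
        idx = rng.choice(n, size=n_sub, replace=False)
        if tune_per_iteration:
            alpha, l1_ratio = _tune(Xa[idx], yv[idx])
        else:
            assert fixed_params is not None
            alpha, l1_ratio = fixed_params
        fit = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000).fit(
            Xa[idx], yv[idx]
        )
        coefs = fit.coef_
        nonzero = frozenset(
            f for f, c in zip(feature_names, coefs) if abs(c) > COEF_ZERO_TOL
        )
        iterations.append((nonzero, dict(zip(feature_names, map(float, coefs)))))

    consensus_sets = [s for s, _ in iterations]
    consensus = set(consensus_sets[0])
    for s in consensus_sets[1:]:
        consensus &= s
    consensus_features = [f for f in feature_names if f in consensus]
    if not consensus_features:
        logger.warning("ensemble produced an empty consensus feature set")
    mean_coefficients = {
        f: float(np.mean([coefs[f] for _, coefs in iterations]))
        for f in consensus_features
    }
    return EnsembleResult(
        iterations=iterations,
        consensus_features=consensus_features,
        mean_coefficients=mean_coefficients,
        n_iter=n_iter,
    )


def consensus_linear_model(
    ens: EnsembleResult,
    X_train: GenomicFeatureMatrix,
    y_train: ScoreVector,
    min_mutations: int = 50,
) -> LinearConsensusModel:
    """Linear model over the consensus features with averaged coefficients.

    The intercept is chosen so the model is unbiased on the training set:
    ``mean(y) - sum_k coef_k * mean(x_k)``. Training feature means are
    stored for Shapley attribution. The same mutation filter used for the
    ensemble is applied.
    """
    if not ens.consensus_features:
        raise ValidationError("consensus feature set is empty; no model to build")
    design = X_train.design_matrix()
    keep = np.ones(len(design), dtype=bool)
    if X_train.n_mutations is not None:
        keep = X_train.n_mutations >= min_mutations
    design = design.loc[keep]
    ymap = dict(zip(y_train.samples, y_train.score))
    yv = np.array([ymap[s] for s, k in zip(X_train.samples, keep) if k])
    missing = [f for f in ens.consensus_features if f not in design.columns]
    if missing:
        raise ValidationError(f"consensus features absent from training matrix: {missing}")
    means = {f: float(design[f].mean()) for f in ens.consensus_features}
    intercept = float(
        yv.mean() - sum(ens.mean_coefficients[f] * means[f] for f in ens.consensus_features)
    )
    return LinearConsensusModel(
        intercept=intercept,
        coefficients=dict(ens.mean_coefficients),
        feature_means=means,
    )


def linear_shap(model: LinearConsensusModel, X: pd.DataFrame | GenomicFeatureMatrix) -> pd.DataFrame:
    """Exact Shapley attributions for a linear model.

    Under the independent-features convention the Shapley value of feature k
    for sample j is ``phi_jk = coef_k * (x_jk - mean_k)``; attributions sum
    to ``prediction_j - prediction_at_the_means``.
    """
    frame = X.design_matrix() if isinstance(X, GenomicFeatureMatrix) else X
    missing = [f for f in model.feature_names if f not in frame.columns]
    if missing:
        raise ValidationError(f"features missing from input: {missing[:10]}")
    coefs = np.array([model.coefficients[f] for f in model.feature_names])
    means = np.array([model.feature_means[f] for f in model.feature_names])
    x = frame[model.feature_names].to_numpy(dtype=float)
    phi = coefs[None, :] * (x - means[None, :])
    return pd.DataFrame(phi, index=frame.index, columns=model.feature_names)


def anova_rf_tissue_model(
    X: GenomicFeatureMatrix,
    labels: StateLabels,
    top_k: int = 30,
    n_splits: int = 5,
    seed: int = 0,
    n_trees: int = 500,
    test_size: float = 0.2,
) -> tuple[list[str], float]:
    """Tissue-specific G0-arrest classifier: ANOVA top-k + random forest.

    Features are ranked by the one-way ANOVA F statistic against the binary
    arrest label; the `top_k` features feed a random forest whose accuracy
    is averaged over `n_splits` random stratified 80/20 train/test splits.
    Returns (selected features, mean accuracy).
    """
    design = X.design_matrix()
    if top_k > design.shape[1]:
        raise ValidationError(f"top_k={top_k} exceeds {design.shape[1]} features")
    lmap = labels.as_mapping()
    y = np.array([lmap[s] for s in X.samples])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValidationError("labels must contain >=2 classes with >=2 samples each")
    f_stat, _ = f_classif(design.to_numpy(dtype=float), y)
    f_stat = np.nan_to_num(f_stat, nan=0.0)
    order = np.argsort(-f_stat, kind="stable")
    selected = [design.columns[i] for i in order[:top_k]]
    xs = design[selected].to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_size, random_state=seed)
    accs = []
    for tr, te in splitter.split(xs, y):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        rf.fit(xs[tr], y[tr])
        accs.append(float(np.mean(rf.predict(xs[te]) == y[te])))
    return selected, float(np.mean(accs))
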