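"""Synthetic data with known ground truth for every stage of the toolkit.

The generators emulate the structure the scoring and modelling methods
assume, with planted truth recorded alongside every matrix:

* two-state cell populations in which the signature's up genes shift up and
  down genes shift down in G0-arrested cells/samples;
* single-cell dropout (Bernoulli zeroing of measured values);
* tissue/study batch offsets;
* bulk purity mixing — a convex combination, on the linear scale, of the
  tumour profile with a fixed normal-tissue profile at weight 1 - purity;
* five stress programmes with programme-specific gene shifts plus labelled
  bulk reference profiles;
* genomic feature matrices with planted linear effects on the G0 score and
  per-sample mutation counts exercising the >=50-mutation filter.

Every generator is a pure function of (config, seed): a single global seed
fans out to independent per-component streams via `numpy` SeedSequence
spawning, so sub-simulations are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .containers import (
    G0,
    PROLIFERATING,
    STRESS_PROGRAMMES,
    ExpressionMatrix,
    GeneSignature,
    PurityVector,
    StateLabels,
    StressSignatureSet,
    ValidationError,
)
from .genomic_dependencies import GenomicFeatureMatrix
from .containers import ScoreVector

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_bulk",
    "simulate_single_cell",
    "simulate_stress",
    "simulate_genomic",
    "simulate_validation_cohort",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the conditions used throughout the test suite: 200
    cells/samples, half of them G0-arrested, signature genes shifted by 3
    log2 units, 20% dropout in single-cell mode, purity uniform on
    [0.3, 1.0] when purity mixing is enabled.
    """

    n_genes: int = 1000
    n_samples: int = 200
    fraction_g0: float = 0.5
    effect_size: float = 3.0
    baseline_loc: float = 4.0    # per-gene mean log2 expression ~ N(loc, scale)
    baseline_scale: float = 1.5
    noise_sd: float = 1.0        # within-gene across-sample SD
    dropout_rate: float = 0.2
    n_batches: int = 1
    batch_offsets: tuple[float, ...] | None = None
    purity_low: float = 0.3
    purity_high: float = 1.0
    apply_purity: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_g0", "dropout_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValidationError("need n_genes >= 1 and n_samples >= 2")
        if not (0 <= self.purity_low <= self.purity_high <= 1):
            raise ValidationError("purity bounds must satisfy 0 <= low <= high <= 1")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset."""

    labels: StateLabels
    programme: dict[str, str] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)
    informative_genes: list[str] = field(default_factory=list)
    purity: PurityVector | None = None


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_universe(cfg: SimulationConfig, sig_genes: list[str]) -> list[str]:
    extra = cfg.n_genes - len(sig_genes)
    background = [f"BG{i:05d}" for i in range(max(extra, 0))]
    return sig_genes + background


def simulate_bulk(
    cfg: SimulationConfig,
    sig: GeneSignature,
    informative: set[str] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-state bulk cohort with signature genes shifted in G0 samples.

    Log2 expression is Normal per gene around a gene-specific baseline;
    G0-arrested samples receive +effect on up genes and -effect on down
    genes. When `informative` is given, only signature genes in that set
    carry the shift — the rest are measured but uninformative (used to
    study signature reduction). Optional batch offsets are added per
    batch, and with ``apply_purity`` the tumour profile is mixed with a
    fixed normal profile on the linear scale at weight 1 - purity.
    """
    rng_base, rng_state, rng_noise, rng_purity = _streams(cfg.seed, 4)
    genes = _gene_universe(cfg, sig.genes)
    n_g, n_s = len(genes), cfg.n_samples
    samples = [f"S{j:04d}" for j in range(n_s)]

    baseline = rng_base.normal(cfg.baseline_loc, cfg.baseline_scale, size=n_g)
    is_g0 = rng_state.random(n_s) < cfg.fraction_g0
    if is_g0.all() or not is_g0.any():
        # single-class cohorts are permitted but most consumers need both
        pass

    values = baseline[:, None] + rng_noise.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    present = set(genes)
    up_genes = [g for g in sig.up if g in present]
    down_genes = [g for g in sig.down if g in present]
    if informative is not None:
        up_genes = [g for g in up_genes if g in informative]
        down_genes = [g for g in down_genes if g in informative]
    truth_informative = up_genes + down_genes
    up_idx = np.array([genes.index(g) for g in up_genes], dtype=int)
    down_idx = np.array([genes.index(g) for g in down_genes], dtype=int)
    if up_idx.size:
        values[np.ix_(up_idx, is_g0)] += cfg.effect_size
    if down_idx.size:
        values[np.ix_(down_idx, is_g0)] -= cfg.effect_size

    batch_labels: list[str] | None = None
    if cfg.n_batches > 1:
        offsets = cfg.batch_offsets or tuple(2.0 * b for b in range(cfg.n_batches))
        batch_assign = np.arange(n_s) % cfg.n_batches
        batch_labels = [f"batch{b}" for b in batch_assign]
        values += np.asarray(offsets)[batch_assign][None, :]

    purity_vec: PurityVector | None = None
    if cfg.apply_purity:
        purity = rng_purity.uniform(cfg.purity_low, cfg.purity_high, size=n_s)
        normal_profile = np.exp2(baseline)  # normal tissue = unshifted baseline
        linear = purity[None, :] * np.exp2(values) + (1 - purity[None, :]) * normal_profile[:, None]
        values = np.log2(linear)
        purity_vec = PurityVector(samples=samples, purity=purity)

    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, log_scale=True)
    labels = StateLabels(
        samples=samples,
        states=[G0 if g else PROLIFERATING for g in is_g0],
        group=batch_labels,
    )
    return expr, SyntheticTruth(
        labels=labels, purity=purity_vec, informative_genes=truth_informative
    )


def simulate_single_cell(
    cfg: SimulationConfig, sig: GeneSignature
) -> tuple[ExpressionMatrix, sparse.csr_matrix, SyntheticTruth]:
    """Single-cell variant: bulk simulation plus Bernoulli dropout.

    Measured values are zeroed independently with probability
    ``dropout_rate``. Returns the dense matrix (zeros in place), its sparse
    CSR form for MatrixMarket export, and the truth.
    """
    expr, truth = simulate_bulk(cfg, sig)
    rng_drop = _streams(cfg.seed, 5)[4]
    values = expr.values.copy()
    if cfg.dropout_rate > 0:
        drop = rng_drop.random(values.shape) < cfg.dropout_rate
        values[drop] = 0.0
    dense = ExpressionMatrix(
        genes=list(expr.genes), samples=list(expr.samples), values=values, log_scale=True
    )
    return dense, sparse.csr_matrix(values), truth


def simulate_stress(
    cfg: SimulationConfig,
    sigs: StressSignatureSet,
    generic: GeneSignature | None = None,
    n_ref_per_programme: int = 5,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str], SyntheticTruth]:
    """Mixed cohort of arrested cells with planted stress programmes.

    A ``fraction_g0`` of cells is arrested; each arrested cell is assigned
    one of the five programmes and receives +effect on that programme's up
    genes and -effect on its down genes. When a `generic` G0 signature is
    given its genes shift in every *arrested* cell (the generic programme
    is shared across all forms of arrest); proliferating cells carry no
    shift, anchoring the cohort baseline the way fast-cycling tumours do.
    Labelled bulk reference profiles (n per programme, lower noise) are
    emitted for kNN classification tests. Returns (query expression,
    reference expression, reference labels, truth); ``truth.programme``
    maps arrested cells only.
    """
    rng_base, rng_assign, rng_noise, rng_ref = _streams(cfg.seed, 4)
    sig_genes: list[str] = []
    pooled = list(sigs.items())
    if generic is not None:
        pooled = pooled + [("generic", generic)]
    for _, s in pooled:
        for g in s.genes:
            if g not in sig_genes:
                sig_genes.append(g)
    genes = _gene_universe(cfg, sig_genes)
    n_g, n_s = len(genes), cfg.n_samples
    samples = [f"C{j:04d}" for j in range(n_s)]
    gene_pos = {g: i for i, g in enumerate(genes)}

    baseline = rng_base.normal(cfg.baseline_loc, cfg.baseline_scale, size=n_g)
    is_g0 = rng_assign.random(n_s) < cfg.fraction_g0
    assignment = rng_assign.integers(0, len(STRESS_PROGRAMMES), size=n_s)
    values = baseline[:, None] + rng_noise.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    gen_up = np.array(
        [gene_pos[g] for g in (generic.up if generic else []) if g in gene_pos], dtype=int
    )
    gen_down = np.array(
        [gene_pos[g] for g in (generic.down if generic else []) if g in gene_pos], dtype=int
    )
    if gen_up.size:
        values[np.ix_(gen_up, is_g0)] += cfg.effect_size
    if gen_down.size:
        values[np.ix_(gen_down, is_g0)] -= cfg.effect_size
    for k, programme in enumerate(STRESS_PROGRAMMES):
        cols = (assignment == k) & is_g0
        s = sigs[programme]
        up = np.array([gene_pos[g] for g in s.up if g in gene_pos], dtype=int)
        down = np.array([gene_pos[g] for g in s.down if g in gene_pos], dtype=int)
        if up.size:
            values[np.ix_(up, cols)] += cfg.effect_size
        if down.size:
            values[np.ix_(down, cols)] -= cfg.effect_size

    ref_samples: list[str] = []
    ref_labels: list[str] = []
    ref_cols: list[np.ndarray] = []
    for programme in STRESS_PROGRAMMES:
        s = sigs[programme]
        up = np.array([gene_pos[g] for g in s.up if g in gene_pos], dtype=int)
        down = np.array([gene_pos[g] for g in s.down if g in gene_pos], dtype=int)
        for i in range(n_ref_per_programme):
            col = baseline + rng_ref.normal(0.0, cfg.noise_sd * 0.5, size=n_g)
            if gen_up.size:
                col[gen_up] += cfg.effect_size
            if gen_down.size:
                col[gen_down] -= cfg.effect_size
            col[up] += cfg.effect_size
            col[down] -= cfg.effect_size
            ref_samples.append(f"ref_{programme}_{i}")
            ref_labels.append(programme)
            ref_cols.append(col)

    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, log_scale=True)
    ref_expr = ExpressionMatrix(
        genes=genes, samples=ref_samples, values=np.column_stack(ref_cols), log_scale=True
    )
    truth = SyntheticTruth(
        labels=StateLabels(
            samples=samples, states=[G0 if g else PROLIFERATING for g in is_g0]
        ),
        programme={
            s: STRESS_PROGRAMMES[a]
            for s, a, g in zip(samples, assignment, is_g0)
            if g
        },
    )
    return expr, ref_expr, ref_labels, truth


def simulate_genomic(
    cfg: SimulationConfig,
    n_features: int = 42,
    true_coefs: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    event_prob: float = 0.3,
    intercept: float = 0.0,
    frac_below_min_mutations: float = 0.1,
    min_mutations: int = 50,
) -> tuple[GenomicFeatureMatrix, ScoreVector, SyntheticTruth]:
    """Binary genomic features with planted linear effects on the G0 score.

    ``y = intercept + X @ beta + Normal(0, noise_sd)`` with beta nonzero only
    on the planted features (default: features 'f1': +2.0 and 'f2': -1.5).
    Mutation counts are drawn so a configurable fraction of samples falls
    below the >=`min_mutations` filter.
    """
    if true_coefs is None:
        true_coefs = {"f1": 2.0, "f2": -1.5}
    rng_x, rng_noise, rng_mut = _streams(cfg.seed, 3)
    n_s = cfg.n_samples
    samples = [f"S{j:04d}" for j in range(n_s)]
    names = [f"f{i + 1}" for i in range(n_features)]
    unknown = [f for f in true_coefs if f not in names]
    if unknown:
        raise ValidationError(f"planted features not in the feature set: {unknown}")

    X = rng_x.binomial(1, event_prob, size=(n_s, n_features)).astype(float)
    beta = np.array([true_coefs.get(f, 0.0) for f in names])
    y = intercept + X @ beta + rng_noise.normal(0.0, noise_sd, size=n_s)

    low = rng_mut.random(n_s) < frac_below_min_mutations
    n_mut = np.where(
        low,
        rng_mut.integers(1, min_mutations, size=n_s),
        rng_mut.integers(min_mutations, 10 * min_mutations, size=n_s),
    )

    features = pd.DataFrame(X, index=samples, columns=names)
    gfm = GenomicFeatureMatrix(
        features=features,
        schema={f: "binary" for f in names},
        n_mutations=n_mut,
    )
    scores = ScoreVector(samples=samples, score=y, method="synthetic_truth")
    truth = SyntheticTruth(
        labels=StateLabels(samples=samples, states=[G0 if v > np.median(y) else PROLIFERATING for v in y]),
        coefficients=dict(true_coefs),
        informative_genes=sorted(true_coefs),
    )
    return gfm, scores, truth


def simulate_validation_cohort(
    cfg: SimulationConfig,
    sig: GeneSignature,
    n_assays: int = 2,
    assay_noise: float = 0.05,
    informative: set[str] | None = None,
) -> tuple[ExpressionMatrix, dict[str, np.ndarray], SyntheticTruth]:
    """Validation cohort with a continuous planted arrest level per sample.

    Each sample's arrest level a_j ~ Uniform(0, 1) scales the signature
    shift (+a_j * effect on up genes, -a_j * effect on down genes); each
    assay measures a_j with additive Gaussian noise. Mirrors cell-line
    cohorts where staining assays quantify the arrested fraction.
    """
    rng_base, rng_level, rng_noise, rng_assay = _streams(cfg.seed, 4)
    genes = _gene_universe(cfg, sig.genes)
    n_g, n_s = len(genes), cfg.n_samples
    samples = [f"V{j:04d}" for j in range(n_s)]
    baseline = rng_base.normal(cfg.baseline_loc, cfg.baseline_scale, size=n_g)
    level = rng_level.uniform(0.0, 1.0, size=n_s)
    values = baseline[:, None] + rng_noise.normal(0.0, cfg.noise_sd, size=(n_g, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    up_genes = [g for g in sig.up if g in gene_pos]
    down_genes = [g for g in sig.down if g in gene_pos]
    if informative is not None:
        up_genes = [g for g in up_genes if g in informative]
        down_genes = [g for g in down_genes if g in informative]
    up = np.array([gene_pos[g] for g in up_genes], dtype=int)
    down = np.array([gene_pos[g] for g in down_genes], dtype=int)
    if up.size:
        values[up, :] += cfg.effect_size * level[None, :]
    if down.size:
        values[down, :] -= cfg.effect_size * level[None, :]
    expr = ExpressionMatrix(genes=genes, samples=samples, values=values, log_scale=True)
    measurements = {
        f"assay_{i}": level + rng_assay.normal(0.0, assay_noise, size=n_s)
        for i in range(n_assays)
    }
    truth = SyntheticTruth(
        labels=StateLabels(
            samples=samples, states=[G0 if v > 0.5 else PROLIFERATING for v in level]
        ),
        informative_genes=up_genes + down_genes,
    )
    return expr, measurements, truth
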