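"""Construction, refinement and I/O of G0-arrest gene signatures.

The generic G0-arrest signature is derived from differential-expression
results contrasting cycling cells with cells in five forms of quiescence
(spontaneous, contact inhibition, serum starvation, CDK4/6 inhibition and
MEK inhibition). Genes significant in *all five* forms, changing in the
*same direction* in all five, not belonging to other cell-cycle stages, and
showing adequate variability/expression plus correlation with DREAM-complex
target expression in a reference cohort make up the signature; the published
version has 139 genes. Stress-programme-specific signatures take, per form,
the 10 most strongly up- and 10 most strongly downregulated genes surviving
the same structural filters.

Vendored data files ship with synthetic placeholder gene identifiers (the
published gene lists live in supplementary tables that are not redistributed
here); the set sizes (139 / 35 / 50) match the published signatures, and the
35-gene minimal signature is a subset of the 139-gene universe.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np

from .containers import (
    STRESS_PROGRAMMES,
    DETable,
    ExpressionMatrix,
    GeneSignature,
    HousekeepingSet,
    StressSignatureSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "load_signature",
    "write_signature",
    "load_housekeeping",
    "generic_signature",
    "minimal_signature",
    "housekeeping_set",
    "refine_signature",
    "build_stress_signatures",
]

_DIRECTIONS = {"up", "down"}


# ---------------------------------------------------------------------------
# Signature file I/O (two-column TSV and GMT dialects)
# ---------------------------------------------------------------------------

def load_signature(path: str | Path, format: str | None = None, name: str | None = None) -> GeneSignature:
    """Load a gene signature from a two-column TSV or a GMT file.

    TSV dialect: header ``gene<TAB>direction`` with direction in
    ``{up, down}``. GMT dialect: one set per line (name, description,
    genes...); two lines per signature with ``_UP`` / ``_DN`` name suffixes.
    Input order is preserved; duplicate (gene, direction) rows collapse.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: empty signature file")
    if format == "gmt":
        return _parse_gmt(text, name or path.stem)
    return _parse_tsv(text, name or path.stem, str(path))


def _parse_tsv(text: str, name: str, where: str) -> GeneSignature:
    up: list[str] = []
    down: list[str] = []
    lines = text.splitlines()
    start = 0
    first = lines[0].rstrip("\n").split("\t")
    if [c.strip().lower() for c in first[:2]] == ["gene", "direction"]:
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{where}:{lineno}: expected 'gene<TAB>direction', got {line!r}")
        gene, direction = parts[0].strip(), parts[1].strip().lower()
        if not gene or direction not in _DIRECTIONS:
            raise ValidationError(
                f"{where}:{lineno}: direction must be 'up' or 'down', got {parts[1]!r}"
            )
        (up if direction == "up" else down).append(gene)
    return GeneSignature(name=name, up=up, down=down)


def _parse_gmt(text: str, name: str) -> GeneSignature:
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"GMT line {lineno}: expected name, description, >=1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    up: list[str] = []
    down: list[str] = []
    for set_name, genes in sets.items():
        upper = set_name.upper()
        if upper.endswith("_UP"):
            up.extend(genes)
        elif upper.endswith("_DN") or upper.endswith("_DOWN"):
            down.extend(genes)
        else:
            raise ValidationError(
                f"GMT set {set_name!r} lacks an _UP/_DN suffix; cannot assign direction"
            )
    return GeneSignature(name=name, up=up, down=down)


def write_signature(sig: GeneSignature, path: str | Path, format: str | None = None) -> None:
    """Write a signature as two-column TSV (default) or GMT."""
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if format == "gmt":
        lines = [
            "\t".join([f"{sig.name}_UP", "up-regulated in G0 arrest"] + sig.up),
            "\t".join([f"{sig.name}_DN", "down-regulated in G0 arrest"] + sig.down),
        ]
        path.write_text("\n".join(lines) + "\n")
        return
    rows = ["gene\tdirection"]
    rows += [f"{g}\tup" for g in sig.up]
    rows += [f"{g}\tdown" for g in sig.down]
    path.write_text("\n".join(rows) + "\n")


def load_housekeeping(path: str | Path) -> HousekeepingSet:
    """Load a housekeeping gene list (one gene per line; optional header)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        g = line.strip().split("\t")[0]
        if g and g.lower() != "gene" and not g.startswith("#"):
            genes.append(g)
    return HousekeepingSet(genes=genes)


def _data_path(filename: str):
    return resources.files("g0kit.data").joinpath(filename)


def generic_signature() -> GeneSignature:
    """The vendored 139-gene generic G0-arrest signature.

    Gene identifiers are synthetic placeholders; sizes and structure match
    the published signature.
    """
    with resources.as_file(_data_path("g0_139_synthetic.tsv")) as p:
        return load_signature(p, name="g0_139")


def minimal_signature() -> GeneSignature:
    """The vendored 35-gene minimal signature (subset of the 139-gene
    universe, for sparse single-cell data). Synthetic placeholder IDs."""
    with resources.as_file(_data_path("g0_35_synthetic.tsv")) as p:
        return load_signature(p, name="g0_35")


def housekeeping_set() -> HousekeepingSet:
    """The vendored housekeeping list (synthetic placeholder IDs)."""
    with resources.as_file(_data_path("housekeeping_synthetic.tsv")) as p:
        return load_housekeeping(p)


# ---------------------------------------------------------------------------
# Refinement filters
# ---------------------------------------------------------------------------

def _expression_filter_fail(
    expr: ExpressionMatrix,
    genes: list[str],
    sd_quantile: float,
    expr_quantile: float,
) -> set[str]:
    """Genes failing the low-SD-or-low-expression filter.

    Thresholds are cohort quantiles computed over *all* genes in `expr`, so
    they do not depend on the candidate list.
    """
    sds = expr.values.std(axis=1, ddof=1)
    means = expr.values.mean(axis=1)
    sd_cut = np.quantile(sds, sd_quantile)
    mean_cut = np.quantile(means, expr_quantile)
    lookup = {g: i for i, g in enumerate(expr.genes)}
    fail = set()
    for g in genes:
        i = lookup[g]
        if sds[i] < sd_cut or means[i] < mean_cut:
            fail.add(g)
    return fail


def _dream_filter_fail(
    expr: ExpressionMatrix,
    genes: list[str],
    dream_targets: set[str],
    dream_abs_corr_min: float,
) -> set[str]:
    """Genes whose |Pearson r| with mean DREAM-target expression is low."""
    dream_idx = expr.gene_index(dream_targets)
    if dream_idx.size == 0:
        logger.warning("no DREAM target genes found in expression matrix; filter skipped")
        return set()
    dream_mean = expr.values[dream_idx, :].mean(axis=0)
    if np.std(dream_mean) == 0:
        logger.warning("DREAM target mean expression is constant; filter skipped")
        return set()
    lookup = {g: i for i, g in enumerate(expr.genes)}
    fail = set()
    for g in genes:
        row = expr.values[lookup[g], :]
        if np.std(row) == 0:
            fail.add(g)
            continue
        r = np.corrcoef(row, dream_mean)[0, 1]
        if abs(r) < dream_abs_corr_min:
            fail.add(g)
    return fail


def refine_signature(
    de: DETable,
    padj_cut: float = 0.05,
    exclusion_list: set[str] | None = None,
    expr: ExpressionMatrix | None = None,
    dream_targets: set[str] | None = None,
    sd_quantile: float = 0.10,
    expr_quantile: float = 0.10,
    dream_abs_corr_min: float = 0.3,
    name: str = "g0_refined",
) -> GeneSignature:
    """Derive a generic G0-arrest signature from five-form DE results.

    Pipeline: (0) keep genes with adjusted p below `padj_cut` in all five
    forms of quiescence; (1) keep genes whose log2 fold change has the same
    sign in all five forms; (2) drop genes in `exclusion_list` (other
    cell-cycle stages); (3) against the reference cohort `expr`, drop genes
    with across-sample SD or mean expression below the given cohort
    quantiles, and genes whose absolute Pearson correlation with the mean
    expression of `dream_targets` falls below `dream_abs_corr_min`.
    Direction is the common fold-change sign.
    """
    if not (0 < sd_quantile < 1 and 0 < expr_quantile < 1):
        raise ValidationError("quantile thresholds must lie in (0, 1)")
    exclusion_list = exclusion_list or set()

    # (0) significant in all five forms
    padj = np.column_stack([de.padj(f).to_numpy() for f in de.forms])
    keep = np.all(padj < padj_cut, axis=1)
    # (1) unidirectional fold change
    fc = np.column_stack([de.log2fc(f).to_numpy() for f in de.forms])
    signs = np.sign(fc)
    keep &= np.all(signs == signs[:, [0]], axis=1) & np.all(signs != 0, axis=1)

    genes = [g for g, k in zip(de.genes, keep) if k]
    direction = {g: ("up" if s > 0 else "down") for g, s in zip(de.genes, signs[:, 0]) if g in set(genes)}

    # (2) explicit exclusions
    genes = [g for g in genes if g not in exclusion_list]

    # (3) cohort-based filters
    if expr is not None:
        if expr.n_samples < 3:
            raise ValidationError("reference cohort needs >=3 samples")
        present = set(expr.genes)
        absent = [g for g in genes if g not in present]
        if absent:
            logger.warning(
                "%d candidate genes absent from the reference cohort were dropped: %s",
                len(absent), absent[:10],
            )
        genes = [g for g in genes if g in present]
        fail = _expression_filter_fail(expr, genes, sd_quantile, expr_quantile)
        if dream_targets:
            fail |= _dream_filter_fail(expr, genes, set(dream_targets), dream_abs_corr_min)
        genes = [g for g in genes if g not in fail]

    up = [g for g in genes if direction[g] == "up"]
    down = [g for g in genes if direction[g] == "down"]
    if not up and not down:
        raise ValidationError("no genes survive the refinement filters")
    return GeneSignature(name=name, up=up, down=down)


def build_stress_signatures(
    de: DETable,
    padj_cut: float = 0.05,
    exclusion_list: set[str] | None = None,
    expr: ExpressionMatrix | None = None,
    sd_quantile: float = 0.10,
    expr_quantile: float = 0.10,
    dream_targets: set[str] | None = None,
    dream_abs_corr_min: float = 0.3,
    n_top: int = 10,
) -> StressSignatureSet:
    """Build the five stress-programme signatures (10 up / 10 down each).

    Per form: genes significant for *that* form only, passing the exclusion
    and cohort filters, ranked by |log2 fold change| for that form; the top
    `n_top` per direction are retained. Ties in |log2fc| at the boundary are
    broken alphabetically by gene identifier for determinism.
    """
    exclusion_list = exclusion_list or set()
    programmes: dict[str, GeneSignature] = {}
    for form in de.forms:
        padj = de.padj(form)
        fc = de.log2fc(form)
        genes = [str(g) for g in de.frame.index[(padj < padj_cut).to_numpy()]]
        genes = [g for g in genes if g not in exclusion_list]
        if expr is not None:
            present = set(expr.genes)
            genes = [g for g in genes if g in present]
            fail = _expression_filter_fail(expr, genes, sd_quantile, expr_quantile)
            if dream_targets:
                fail |= _dream_filter_fail(expr, genes, set(dream_targets), dream_abs_corr_min)
            genes = [g for g in genes if g not in fail]
        fc_map = fc.to_dict()
        chosen: dict[str, list[str]] = {}
        for dir_name, pool in (
            ("up", [g for g in genes if fc_map[g] > 0]),
            ("down", [g for g in genes if fc_map[g] < 0]),
        ):
            if len(pool) < n_top:
                raise ValidationError(
                    f"stress programme {form!r}: only {len(pool)} {dir_name}-regulated "
                    f"genes survive filtering; {n_top} required"
                )
            ranked = sorted(pool, key=lambda g: (-abs(fc_map[g]), g))
            chosen[dir_name] = ranked[:n_top]
        programmes[form] = GeneSignature(name=form, up=chosen["up"], down=chosen["down"])
    return StressSignatureSet(programmes=programmes)
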