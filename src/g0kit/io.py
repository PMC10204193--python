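"""Readers and writers for the toolkit's plain-text formats.

Bulk expression travels as TSV/CSV with genes in rows, a header row of
sample IDs and gene IDs in the first column. Single-cell expression uses
MatrixMarket triplets plus one-ID-per-line ``genes.tsv`` / ``barcodes.tsv``
companions. Scores, labels, purity and genomic feature matrices are TSV;
the consensus linear model serialises to JSON. TSV is the canonical output
dialect (UTF-8, '.' decimal, floats at 6 significant digits); CSV is
accepted on input only.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import (
    ExpressionMatrix,
    PurityVector,
    ScoreVector,
    StateLabels,
    ValidationError,
)
from .genomic_dependencies import GenomicFeatureMatrix, LinearConsensusModel

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "write_expression_mtx",
    "read_scores",
    "write_scores",
    "read_labels",
    "write_labels",
    "read_purity",
    "read_feature_matrix",
    "write_model",
    "read_model",
]

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    format: str | None = None,
    log_scale: bool = True,
    genes_file: str | Path | None = None,
    barcodes_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or MatrixMarket triplet.

    For ``mtx`` input the companion files default to ``genes.tsv`` and
    ``barcodes.tsv`` next to the matrix. Duplicate gene or sample IDs are
    an error.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"csv": "csv", "mtx": "mtx"}.get(suffix.lstrip("."), "tsv")
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"{path}: duplicate gene rows: {dups[:10]}")
        return ExpressionMatrix.from_frame(frame, log_scale=log_scale)
    if format != "mtx":
        raise ValidationError(f"unknown expression format {format!r}")
    genes_file = Path(genes_file) if genes_file else path.parent / "genes.tsv"
    barcodes_file = Path(barcodes_file) if barcodes_file else path.parent / "barcodes.tsv"
    matrix = scipy_io.mmread(path)
    genes = [ln.split("\t")[0] for ln in genes_file.read_text().splitlines() if ln.strip()]
    cells = [ln.split("\t")[0] for ln in barcodes_file.read_text().splitlines() if ln.strip()]
    if matrix.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"{path}: matrix is {matrix.shape[0]}x{matrix.shape[1]} but index files "
            f"list {len(genes)} genes and {len(cells)} barcodes"
        )
    dense = np.asarray(matrix.todense()) if sparse.issparse(matrix) else np.asarray(matrix)
    return ExpressionMatrix(genes=genes, samples=cells, values=dense, log_scale=log_scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_expression_mtx(expr: ExpressionMatrix, out_dir: str | Path, name: str = "matrix") -> None:
    """Write a matrix as MatrixMarket triplet plus gene/barcode index files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(out_dir / f"{name}.mtx", sparse.csr_matrix(expr.values))
    (out_dir / "genes.tsv").write_text("\n".join(expr.genes) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(expr.samples) + "\n")


# ---------------------------------------------------------------------------
# Scores, labels, purity
# ---------------------------------------------------------------------------

def write_scores(scores: ScoreVector, path: str | Path) -> None:
    """Scores TSV: ``sample  score  n_up_used  n_down_used``."""
    with open(path, "w") as fh:
        fh.write("sample\tscore\tn_up_used\tn_down_used\n")
        for s, v in zip(scores.samples, scores.score):
            fh.write(f"{s}\t{v:.6g}\t{scores.n_up_used}\t{scores.n_down_used}\n")


def read_scores(path: str | Path, method: str = "loaded") -> ScoreVector:
    frame = pd.read_csv(path, sep="\t")
    if "sample" not in frame.columns or "score" not in frame.columns:
        raise ValidationError(f"{path}: expected columns 'sample' and 'score'")
    n_up = int(frame["n_up_used"].iloc[0]) if "n_up_used" in frame.columns and len(frame) else 0
    n_down = int(frame["n_down_used"].iloc[0]) if "n_down_used" in frame.columns and len(frame) else 0
    return ScoreVector(
        samples=[str(s) for s in frame["sample"]],
        score=frame["score"].to_numpy(dtype=float) if len(frame) else np.empty(0),
        method=method,
        n_up_used=n_up,
        n_down_used=n_down,
    )


def write_labels(labels: StateLabels, path: str | Path) -> None:
    labels.to_frame().to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> StateLabels:
    frame = pd.read_csv(path, sep="\t")
    if "sample" not in frame.columns or "state" not in frame.columns:
        raise ValidationError(f"{path}: expected columns 'sample' and 'state'")
    return StateLabels(
        samples=[str(s) for s in frame["sample"]],
        states=[str(s) for s in frame["state"]],
        group=[str(g) for g in frame["group"]] if "group" in frame.columns else None,
    )


def read_purity(path: str | Path) -> PurityVector:
    frame = pd.read_csv(path, sep="\t")
    if "sample" not in frame.columns or "purity" not in frame.columns:
        raise ValidationError(f"{path}: expected columns 'sample' and 'purity'")
    return PurityVector(
        samples=[str(s) for s in frame["sample"]],
        purity=frame["purity"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Genomic features and models
# ---------------------------------------------------------------------------

def read_feature_matrix(
    path: str | Path, schema_path: str | Path, n_mutations_col: str = "n_mutations"
) -> GenomicFeatureMatrix:
    """Read a samples-in-rows feature TSV plus its sidecar type schema.

    The schema TSV has columns ``feature`` and ``type`` (binary, continuous
    or categorical). A column named `n_mutations_col`, if present, is pulled
    out as the per-sample mutation count.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    schema_frame = pd.read_csv(schema_path, sep="\t")
    if "feature" not in schema_frame.columns or "type" not in schema_frame.columns:
        raise ValidationError(f"{schema_path}: expected columns 'feature' and 'type'")
    schema = dict(zip(schema_frame["feature"].astype(str), schema_frame["type"].astype(str)))
    n_mut = None
    if n_mutations_col in frame.columns:
        n_mut = frame.pop(n_mutations_col).to_numpy()
        schema.pop(n_mutations_col, None)
    return GenomicFeatureMatrix(features=frame, schema=schema, n_mutations=n_mut)


def write_model(model: LinearConsensusModel, path: str | Path) -> None:
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "feature_means": model.feature_means,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_model(path: str | Path) -> LinearConsensusModel:
    payload = json.loads(Path(path).read_text())
    return LinearConsensusModel(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        feature_means={k: float(v) for k, v in payload["feature_means"].items()},
    )
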