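"""Core in-memory containers shared across the toolkit.

The central substrate is :class:`ExpressionMatrix`, a genes x samples (or
cells) matrix of expression values with an explicit log-scale flag; every
scoring and classification routine consumes it. Gene signatures are held as
named, disjoint up/down gene lists (:class:`GeneSignature`), and per-sample
outputs travel as :class:`ScoreVector` / :class:`StateLabels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "HousekeepingSet",
    "DETable",
    "StressSignatureSet",
    "ScoreVector",
    "PurityVector",
    "StateLabels",
    "STRESS_PROGRAMMES",
    "G0",
    "PROLIFERATING",
    "UNCERTAIN",
    "ValidationError",
]

#: The five stress programmes that induce G0 arrest, in canonical order.
STRESS_PROGRAMMES: tuple[str, ...] = (
    "spontaneous",
    "contact_inhibition",
    "serum_starvation",
    "cdk46_inhibition",
    "mek_inhibition",
)

G0 = "G0"
PROLIFERATING = "proliferating"
UNCERTAIN = "uncertain"


class ValidationError(ValueError):
    """Raised when an input violates a container or operation contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    Parameters
    ----------
    genes, samples
        Ordered, unique identifiers for rows and columns.
    values
        Real matrix of shape ``(len(genes), len(samples))``; all finite.
    log_scale
        Whether ``values`` are on log2 scale. Operations that must act on
        the linear scale (purity adjustment, purity mixing) honour this flag.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.samples, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")

    # -- conversion helpers -------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, log_scale: bool = True) -> "ExpressionMatrix":
        return cls(
            genes=[str(g) for g in frame.index],
            samples=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            log_scale=log_scale,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Row indices of the subset of `genes` present in the matrix."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = [lookup[s] for s in keep]
        return ExpressionMatrix(
            genes=list(self.genes),
            samples=list(keep),
            values=self.values[:, idx],
            log_scale=self.log_scale,
        )

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in keep if g in set(self.genes)]
        idx = self.gene_index(present)
        return ExpressionMatrix(
            genes=present,
            samples=list(self.samples),
            values=self.values[idx, :],
            log_scale=self.log_scale,
        )


@dataclass
class GeneSignature:
    """A named gene signature with disjoint up- and down-regulated lists."""

    name: str
    up: list[str] = field(default_factory=list)
    down: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.up = list(dict.fromkeys(self.up))
        self.down = list(dict.fromkeys(self.down))
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValidationError(
                f"signature '{self.name}': genes in both up and down lists: "
                f"{sorted(overlap)[:10]}"
            )
        if not self.up and not self.down:
            raise ValidationError(f"signature '{self.name}' is empty")

    def __len__(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def genes(self) -> list[str]:
        return self.up + self.down

    def restrict(self, genes: Iterable[str], name: str | None = None) -> "GeneSignature":
        """Signature restricted to `genes`, directions preserved."""
        keep = set(genes)
        return GeneSignature(
            name=name or f"{self.name}_subset",
            up=[g for g in self.up if g in keep],
            down=[g for g in self.down if g in keep],
        )


@dataclass
class HousekeepingSet:
    """Stably expressed genes used to normalise the mean-scaled G0 score."""

    genes: list[str]

    def __post_init__(self) -> None:
        self.genes = list(dict.fromkeys(self.genes))
        if not self.genes:
            raise ValidationError("housekeeping set is empty")


@dataclass
class DETable:
    """Differential-expression results (quiescent vs cycling) for the five
    forms of quiescence.

    Wraps a frame indexed by gene with columns ``log2fc_<form>`` and
    ``padj_<form>`` for every form in :data:`STRESS_PROGRAMMES`.
    """

    frame: pd.DataFrame
    forms: tuple[str, ...] = STRESS_PROGRAMMES

    def __post_init__(self) -> None:
        missing = [
            c
            for f in self.forms
            for c in (f"log2fc_{f}", f"padj_{f}")
            if c not in self.frame.columns
        ]
        if missing:
            raise ValidationError(f"DE table missing columns: {missing}")
        if self.frame.index.has_duplicates:
            raise ValidationError("DE table has duplicate gene rows")
        padj = self.frame[[f"padj_{f}" for f in self.forms]].to_numpy()
        if np.any((padj < 0) | (padj > 1)):
            raise ValidationError("adjusted p-values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    def log2fc(self, form: str) -> pd.Series:
        return self.frame[f"log2fc_{form}"]

    def padj(self, form: str) -> pd.Series:
        return self.frame[f"padj_{form}"]


@dataclass
class StressSignatureSet:
    """One 10-up/10-down gene signature per stress programme."""

    programmes: dict[str, GeneSignature]

    def __post_init__(self) -> None:
        if set(self.programmes) != set(STRESS_PROGRAMMES):
            raise ValidationError(
                f"expected programmes {sorted(STRESS_PROGRAMMES)}, "
                f"got {sorted(self.programmes)}"
            )

    def __getitem__(self, programme: str) -> GeneSignature:
        return self.programmes[programme]

    def items(self):
        return ((p, self.programmes[p]) for p in STRESS_PROGRAMMES)


@dataclass
class ScoreVector:
    """Per-sample signature scores plus bookkeeping on gene dropout."""

    samples: list[str]
    score: np.ndarray
    method: str
    n_up_used: int = 0
    n_down_used: int = 0

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.samples),):
            raise ValidationError("score length does not match samples")

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.samples, name=self.method)


@dataclass
class PurityVector:
    """Per-sample tumour purity estimates in [0, 1]."""

    samples: list[str]
    purity: np.ndarray

    def __post_init__(self) -> None:
        self.purity = np.asarray(self.purity, dtype=float)
        if self.purity.shape != (len(self.samples),):
            raise ValidationError("purity length does not match samples")
        if np.any((self.purity < 0) | (self.purity > 1)):
            raise ValidationError("purity values must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.purity, index=self.samples, name="purity")


@dataclass
class StateLabels:
    """A complete labelling of samples/cells, optionally grouped."""

    samples: list[str]
    states: list[str]
    group: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.states) != len(self.samples):
            raise ValidationError("states length does not match samples")
        if self.group is not None and len(self.group) != len(self.samples):
            raise ValidationError("group length does not match samples")

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list[str]] = {"sample": self.samples, "state": self.states}
        if self.group is not None:
            data["group"] = self.group
        return pd.DataFrame(data)

    def as_mapping(self) -> Mapping[str, str]:
        return dict(zip(self.samples, self.states))
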