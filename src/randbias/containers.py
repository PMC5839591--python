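"""In-memory domain containers shared by every pipeline stage.

All downstream modules operate on these validated types only; file parsing
lives in :mod:`randbias.io`. Expression follows the TCGA level-3 convention
of genes in rows and samples in columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("randbias")

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneList",
    "ClinicalLabels",
    "align_expression_survival",
]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``. Must be free of
        missing entries; non-negative unless ``log_transformed``.
    gene_ids, sample_ids
        Ordered, unique identifiers for the rows / columns.
    log_transformed
        Whether values are on a log2(x+1) scale (negative entries allowed).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        bad = ~np.isfinite(self.values)
        if bad.any():
            rows = np.flatnonzero(bad.any(axis=1))
            names = [self.gene_ids[i] for i in rows[:10]]
            raise ValueError(f"missing/non-finite expression for genes: {names}")
        if not self.log_transformed and (self.values < 0).any():
            rows = np.flatnonzero((self.values < 0).any(axis=1))
            names = [self.gene_ids[i] for i in rows[:10]]
            raise ValueError(
                f"negative values in non-log-transformed matrix (genes {names})"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[indices],
            [self.gene_ids[i] for i in indices],
            list(self.sample_ids),
            self.log_transformed,
        )

    def subset_samples(self, indices: np.ndarray) -> "ExpressionMatrix":
        indices = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, indices],
            list(self.gene_ids),
            [self.sample_ids[i] for i in indices],
            self.log_transformed,
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time and event indicator (1=event, 0=censored)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        _check_unique(self.sample_ids, "sample ids")
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if not np.isfinite(self.time).all() or (self.time < 0).any():
            raise ValueError("follow-up times must be finite and non-negative")
        ev = np.asarray(self.event, dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")
        self.event = ev.astype(int)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, indices: np.ndarray) -> "SurvivalTable":
        indices = np.asarray(indices, dtype=int)
        return SurvivalTable(
            [self.sample_ids[i] for i in indices],
            self.time[indices],
            self.event[indices],
        )


@dataclass
class GeneList:
    """Ordered signature gene symbols; duplicates dropped with a warning."""

    gene_ids: list[str]

    def __post_init__(self) -> None:
        cleaned = [str(g).strip() for g in self.gene_ids if str(g).strip()]
        if not cleaned:
            raise ValueError("gene list is empty")
        seen: set[str] = set()
        unique: list[str] = []
        for g in cleaned:
            if g not in seen:
                unique.append(g)
                seen.add(g)
        n_dup = len(cleaned) - len(unique)
        if n_dup:
            warnings.warn(f"{n_dup} duplicate gene symbol(s) removed", stacklevel=2)
        self.gene_ids = unique

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class ClinicalLabels:
    """Categorical per-sample labels (e.g. tumour grade); missing allowed.

    Missing labels are encoded as ``None``.
    """

    sample_ids: list[str]
    labels: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample ids")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length must match sample_ids")
        self.labels = [
            None if (x is None or str(x).strip() in ("", "NA", "nan")) else str(x)
            for x in self.labels
        ]


def align_expression_survival(
    expr: ExpressionMatrix, surv: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Align an expression matrix and a survival table on shared sample ids.

    TCGA clinical and expression tables routinely cover slightly different
    sample sets, so a mismatch resolves to the intersection (in expression
    column order) with a logged warning; an empty intersection is an error.
    """
    if expr.sample_ids == surv.sample_ids:
        return expr, surv
    surv_idx = {s: i for i, s in enumerate(surv.sample_ids)}
    keep = [i for i, s in enumerate(expr.sample_ids) if s in surv_idx]
    if not keep:
        raise ValueError("expression and survival share no sample ids")
    dropped = (expr.n_samples - len(keep)) + (surv.n_samples - len(keep))
    if dropped:
        logger.warning(
            "sample id mismatch: keeping %d shared samples (%d dropped)",
            len(keep), dropped,
        )
    expr2 = expr.subset_samples(np.asarray(keep))
    surv2 = surv.subset(np.asarray([surv_idx[expr.sample_ids[i]] for i in keep]))
    return expr2, surv2
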