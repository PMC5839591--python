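"""Proliferation scoring and expression residualization.

A per-sample proliferation score is the median expression over a signature
gene list (canonically the genes most correlated with PCNA). Each gene is
then replaced by its residual from an ordinary-least-squares fit on the
score, removing the proliferation component from the whole matrix. Scores
are always computed from unadjusted expression; adjusted matrices never feed
score computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix, GeneList

logger = logging.getLogger("randbias")

__all__ = [
    "ProliferationScore",
    "AdjustedExpression",
    "proliferation_score",
    "derive_signature_from_anchor",
    "adjust_expression",
]


@dataclass
class ProliferationScore:
    sample_ids: list[str]
    score: np.ndarray
    n_signature_genes_used: int
    n_signature_genes_missing: int

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("score length must match sample_ids")


@dataclass
class AdjustedExpression:
    residuals: ExpressionMatrix
    per_gene_intercept: np.ndarray
    per_gene_slope: np.ndarray

    @property
    def expression(self) -> ExpressionMatrix:
        return self.residuals


def proliferation_score(
    expr: ExpressionMatrix, signature: GeneList
) -> ProliferationScore:
    """Median expression over the present signature genes, per sample."""
    index = expr.gene_index()
    present = [g for g in signature.gene_ids if g in index]
    n_missing = len(signature.gene_ids) - len(present)
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    if n_missing:
        logger.warning("%d signature genes absent from the matrix", n_missing)
    rows = np.asarray([index[g] for g in present])
    score = np.median(expr.values[rows], axis=0)
    return ProliferationScore(list(expr.sample_ids), score, len(present), n_missing)


def derive_signature_from_anchor(
    expr: ExpressionMatrix, anchor_gene: str, top_fraction: float = 0.01
) -> GeneList:
    """Genes most Pearson-correlated with an anchor gene across samples.

    An in-dataset stand-in for a published cross-dataset signature: the top
    ``ceil(top_fraction * n_genes)`` genes by correlation with the anchor
    (anchor excluded) are returned.
    """
    if not 0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must be in (0, 0.5]")
    index = expr.gene_index()
    if anchor_gene not in index:
        raise ValueError(f"anchor gene {anchor_gene!r} not in matrix")
    a = expr.values[index[anchor_gene]]
    if np.ptp(a) == 0:
        raise ValueError("anchor gene has zero variance")
    X = expr.values - expr.values.mean(axis=1, keepdims=True)
    ac = a - a.mean()
    denom = np.sqrt((X**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X @ ac) / denom
    r[~np.isfinite(r)] = -np.inf  # constant genes can never rank
    r[index[anchor_gene]] = -np.inf
    n_top = int(np.ceil(top_fraction * expr.n_genes))
    top = np.argsort(-r, kind="stable")[:n_top]
    return GeneList([expr.gene_ids[i] for i in top])


def adjust_expression(
    expr: ExpressionMatrix, score: ProliferationScore
) -> AdjustedExpression:
    """Replace each gene by its OLS residual against the proliferation score."""
    if score.sample_ids != expr.sample_ids:
        raise ValueError("score and expression sample ids differ")
    s = score.score
    if np.ptp(s) == 0:
        raise ValueError("constant proliferation score: fit undefined")
    sc = s - s.mean()
    Xm = expr.values.mean(axis=1)
    Xc = expr.values - Xm[:, None]
    slope = (Xc @ sc) / (sc @ sc)
    intercept = Xm - slope * s.mean()
    residuals = Xc - slope[:, None] * sc[None, :]
    out = ExpressionMatrix(
        residuals, list(expr.gene_ids), list(expr.sample_ids), log_transformed=True
    )
    return AdjustedExpression(out, intercept, slope)
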