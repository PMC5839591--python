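"""Half-split consistency of random gene-set prognostic power.

The cohort is split into two random halves (independent fair coin per
sample); a batch of random gene sets is evaluated in both halves and a set
is called significant in a half when its raw log-rank p-value falls below a
nominal threshold. Pooling over many splits, a 2x2 table of significant-in-A
by significant-in-B is tested for enrichment of doubly-significant sets with
a one-sided Fisher exact test — random sets that are genuinely prognostic
replicate across halves far more often than independence predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bias import _pc1, median_split, sample_gene_set
from .containers import ExpressionMatrix, SurvivalTable, align_expression_survival
from .stats import TwoByTwoTable, batch_logrank, fisher_exact

logger = logging.getLogger("randbias")

__all__ = ["ConsistencyResult", "bernoulli_half_split", "consistency_analysis"]


@dataclass
class ConsistencyResult:
    n_splits: int
    sets_per_split: int
    set_size: int
    per_half_signif_prop: float
    repeat_prop: float
    odds_ratio: float
    fisher_p: float
    n_both: int
    n_a_only: int
    n_b_only: int
    n_neither: int


def bernoulli_half_split(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean half assignment: each sample independently heads/tails.

    Redraws (with a logged count) in the pathological case of an empty half.
    """
    if n_samples < 8:
        raise ValueError("need at least 8 samples to split")
    redraws = 0
    while True:
        mask = rng.random(n_samples) < 0.5
        if 0 < mask.sum() < n_samples:
            if redraws:
                logger.warning("redrew %d empty half-splits", redraws)
            return mask
        redraws += 1


def _half_pvalues(
    values: np.ndarray,
    surv: SurvivalTable,
    gene_sets: list[np.ndarray],
    half: np.ndarray,
) -> np.ndarray:
    """Log-rank p for each gene set inside one half of the cohort."""
    idx = np.flatnonzero(half)
    sub_surv = surv.subset(idx)
    labels = np.empty((len(gene_sets), len(idx)), dtype=bool)
    for i, gs in enumerate(gene_sets):
        labels[i] = median_split(_pc1(values[np.ix_(gs, idx)]))
    _, p = batch_logrank(labels, sub_surv.time, sub_surv.event)
    return p


def consistency_analysis(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    set_size: int = 64,
    n_splits: int = 50,
    sets_per_split: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> ConsistencyResult:
    """Pooled half-split replication analysis of random gene sets.

    For each of ``n_splits`` random halvings, ``sets_per_split`` fresh random
    gene sets are scored in both halves; significance per half is ``p <
    alpha`` on the raw log-rank p. The pooled 2x2 table over all
    ``n_splits * sets_per_split`` sets gives the odds ratio and one-sided
    Fisher p. Splits leaving a half with no events (or too few samples to
    split at the median) are redrawn with a logged count.
    """
    if sets_per_split < 1 or n_splits < 1:
        raise ValueError("n_splits and sets_per_split must be >= 1")
    expr, surv = align_expression_survival(expr, surv)
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    sig_a = []
    sig_b = []
    redraws = 0
    for _ in range(n_splits):
        while True:
            half = bernoulli_half_split(n, rng)
            if (
                min(half.sum(), (~half).sum()) >= 4
                and surv.event[half].sum() > 0
                and surv.event[~half].sum() > 0
            ):
                break
            redraws += 1
        gene_sets = [
            sample_gene_set(expr.n_genes, set_size, rng) for _ in range(sets_per_split)
        ]
        pa = _half_pvalues(expr.values, surv, gene_sets, half)
        pb = _half_pvalues(expr.values, surv, gene_sets, ~half)
        sig_a.append(pa < alpha)
        sig_b.append(pb < alpha)
    if redraws:
        logger.warning("redrew %d splits with an event-free or tiny half", redraws)
    A = np.concatenate(sig_a)
    B = np.concatenate(sig_b)
    n_both = int((A & B).sum())
    n_a = int((A & ~B).sum())
    n_b = int((~A & B).sum())
    n_neither = int((~A & ~B).sum())
    table = TwoByTwoTable(n_both, n_a, n_b, n_neither)
    odds_ratio, fisher_p = fisher_exact(table, side="greater")
    total = len(A)
    return ConsistencyResult(
        n_splits=n_splits,
        sets_per_split=sets_per_split,
        set_size=set_size,
        per_half_signif_prop=float((A.mean() + B.mean()) / 2.0),
        repeat_prop=n_both / total,
        odds_ratio=odds_ratio,
        fisher_p=fisher_p,
        n_both=n_both,
        n_a_only=n_a,
        n_b_only=n_b,
        n_neither=n_neither,
    )
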