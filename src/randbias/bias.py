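"""The random-bias resampling statistic.

For a gene-set size *s*, draw *b* uniform random gene subsets; summarize each
subset by the samples' first-principal-component scores, split the cohort at
the median score, and record the two-group log-rank p-value (the set P). An
empirical null R is built from *b* uniformly random equal-sized group
assignments of the same samples — this captures follow-up sparsity and tied
event times that make the nominal chi-square reference unreliable. The
proportion of P below the 5th percentile of R is the *proportion of
significant random sets*; its deviation from 0.05 is tested with a
two-proportion Z statistic

    Z = (p_hat - 0.05) / sqrt(p_hat (1 - p_hat)/b + 0.05 * 0.95 / b)

referred to N(0,1). A dataset is positively biased when significantly above
0.05 and negatively biased when significantly below.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import ExpressionMatrix, SurvivalTable, align_expression_survival
from .stats import batch_logrank, empirical_percentile

logger = logging.getLogger("randbias")

__all__ = [
    "PValueSample",
    "BiasResult",
    "BiasProfile",
    "DEFAULT_SET_SIZES",
    "sample_gene_set",
    "pc1_scores",
    "median_split",
    "random_set_pvalues",
    "null_pvalues",
    "significant_proportion",
    "proportion_z_test",
    "run_bias_analysis",
    "pvalue_diagnostics",
]

DEFAULT_SET_SIZES: tuple[int, ...] = tuple(2**k for k in range(11))


@dataclass
class PValueSample:
    """A batch of resampled log-rank p-values (P or R)."""

    p_values: np.ndarray
    set_size: int
    b: int
    seed: int
    source: str  # random_gene_sets | null_assignments

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.p_values.shape != (self.b,):
            raise ValueError("p_values length must equal b")
        if ((self.p_values < 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class BiasResult:
    """One (set size, dataset) row of the bias analysis."""

    set_size: int
    b: int
    threshold_r: float
    prop_signif: float
    z: float
    p_two_sided: float
    direction: str  # positive | negative | none


@dataclass
class BiasProfile:
    """Bias results across a sweep of set sizes for one dataset."""

    results: list[BiasResult]
    dataset_label: str = ""
    adjusted: bool = False

    def __post_init__(self) -> None:
        sizes = [r.set_size for r in self.results]
        if sizes != sorted(set(sizes)):
            raise ValueError("set sizes must be strictly increasing")

    def at_size(self, set_size: int) -> BiasResult:
        for r in self.results:
            if r.set_size == set_size:
                return r
        raise KeyError(f"no result at set size {set_size}")


def sample_gene_set(
    n_genes: int, set_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random subset of gene indices, without replacement."""
    if not 1 <= set_size <= n_genes:
        raise ValueError(f"set_size {set_size} out of range [1, {n_genes}]")
    return rng.choice(n_genes, size=set_size, replace=False)


def _pc1(values: np.ndarray) -> np.ndarray:
    """First right singular vector of a row-centered genes x samples matrix.

    Zero-variance gene rows are dropped; raises if all rows are constant.
    The returned score vector has unit norm; its sign is unconstrained (the
    downstream median split is sign-invariant).
    """
    X = np.asarray(values, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    keep = (X != 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes have zero variance")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("dropped %d zero-variance genes from PC1", n_dropped)
        X = X[keep]
    s, n = X.shape
    if s <= n:
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        return vt[0]
    # wide-in-genes case: leading eigenvector of the sample Gram matrix
    gram = X.T @ X
    w, v = np.linalg.eigh(gram)
    return v[:, -1]


def pc1_scores(submatrix: ExpressionMatrix) -> np.ndarray:
    """Per-sample scores on the first principal component of a gene subset."""
    if submatrix.n_samples < 2:
        raise ValueError("need at least two samples")
    return _pc1(submatrix.values)


def median_split(scores: np.ndarray) -> np.ndarray:
    """Split samples at the median score into two near-equal groups.

    Returns a boolean vector, ``True`` for the high-score group. Samples
    strictly below the median go low, strictly above go high; samples exactly
    at the median are assigned deterministically in input order to whichever
    group is currently smaller (low when equal), keeping sizes within one.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate scores: all identical")
    med = np.median(scores)
    high = scores > med
    n_high = int(high.sum())
    n_low = int((scores < med).sum())
    for i in np.flatnonzero(scores == med):
        if n_high < n_low:
            high[i] = True
            n_high += 1
        else:
            n_low += 1
    return high


def random_set_pvalues(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    set_size: int,
    b: int,
    seed: int,
) -> PValueSample:
    """The set P: b draws of random gene set -> PC1 -> median split -> log-rank.

    Degenerate draws (fully zero-variance submatrix or constant scores) are
    redrawn with a logged count so exactly *b* valid p-values are produced.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    expr, surv = align_expression_survival(expr, surv)
    if surv.n_events == 0:
        raise ValueError("no events in survival table")
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    labels = np.empty((b, n), dtype=bool)
    redraws = 0
    for i in range(b):
        while True:
            idx = sample_gene_set(expr.n_genes, set_size, rng)
            try:
                scores = _pc1(expr.values[idx])
                labels[i] = median_split(scores)
                break
            except ValueError:
                redraws += 1
                if redraws > 100 * b:
                    raise
    if redraws:
        logger.warning("redrew %d degenerate gene sets", redraws)
    _, pvals = batch_logrank(labels, surv.time, surv.event)
    return PValueSample(pvals, set_size, b, seed, "random_gene_sets")


def _random_half_labels(n: int, b: int, rng: np.random.Generator) -> np.ndarray:
    """b uniformly random equal-sized partitions (sizes ceil/floor n/2)."""
    labels = np.zeros((b, n), dtype=bool)
    n_high = n // 2  # mirrors median_split: high group gets floor(n/2)
    for i in range(b):
        labels[i, rng.choice(n, size=n_high, replace=False)] = True
    return labels


def null_pvalues(surv: SurvivalTable, b: int, seed: int) -> PValueSample:
    """The empirical null R: log-rank p-values of random equal-sized splits.

    Depends only on the survival table, so one R per dataset serves every
    gene-set size.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if surv.n_events == 0:
        raise ValueError("no events in survival table")
    rng = np.random.default_rng(seed)
    labels = _random_half_labels(surv.n_samples, b, rng)
    _, pvals = batch_logrank(labels, surv.time, surv.event)
    return PValueSample(pvals, 0, b, seed, "null_assignments")


def significant_proportion(
    P: PValueSample, R: PValueSample
) -> tuple[float, float]:
    """Null 5th-percentile threshold and the proportion of P strictly below it."""
    threshold_r = empirical_percentile(R.p_values, 5.0)
    prop = float((P.p_values < threshold_r).mean())
    return threshold_r, prop


def proportion_z_test(prop_signif: float, b: int) -> tuple[float, float]:
    """Two-proportion Z test of the significant proportion against 0.05.

    The null variance pools the observed proportion and the nominal 0.05,
    each over the b draws; under no bias Z ~ N(0,1).
    """
    if b < 2:
        raise ValueError("b must be >= 2")
    if not 0 <= prop_signif <= 1:
        raise ValueError("prop_signif must be in [0, 1]")
    se = np.sqrt(prop_signif * (1 - prop_signif) / b + 0.05 * 0.95 / b)
    z = (prop_signif - 0.05) / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def _classify(prop_signif: float, p_two_sided: float, alpha: float = 0.05) -> str:
    if p_two_sided < alpha and prop_signif > 0.05:
        return "positive"
    if p_two_sided < alpha and prop_signif < 0.05:
        return "negative"
    return "none"


def bias_result_from_samples(P: PValueSample, R: PValueSample) -> BiasResult:
    """Assemble one BiasResult from a (P, R) pair."""
    threshold_r, prop = significant_proportion(P, R)
    z, p2 = proportion_z_test(prop, P.b)
    return BiasResult(P.set_size, P.b, threshold_r, prop, z, p2, _classify(prop, p2))


def run_bias_analysis(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    set_sizes: tuple[int, ...] = DEFAULT_SET_SIZES,
    b: int = 5000,
    seed: int = 0,
    dataset_label: str = "",
    adjusted: bool = False,
) -> BiasProfile:
    """Full size sweep: one shared null R, one BiasResult per set size."""
    if len(set_sizes) == 0:
        raise ValueError("set_sizes must be non-empty")
    expr, surv = align_expression_survival(expr, surv)
    seeds = np.random.SeedSequence(seed).generate_state(len(set_sizes) + 1) % (2**31)
    R = null_pvalues(surv, b, int(seeds[0]))
    results = []
    for i, s in enumerate(sorted(set_sizes)):
        P = random_set_pvalues(expr, surv, s, b, int(seeds[i + 1]))
        results.append(bias_result_from_samples(P, R))
    return BiasProfile(results, dataset_label=dataset_label, adjusted=adjusted)


def pvalue_diagnostics(P: PValueSample, R: PValueSample) -> dict:
    """Numeric diagnostics of P against R: histogram, QQ pairs, CDF points."""
    if P.b == 0 or R.b == 0:
        raise ValueError("empty p-value samples")
    edges = np.linspace(0.0, 1.0, 21)
    hist_P, _ = np.histogram(P.p_values, bins=edges)
    hist_R, _ = np.histogram(R.p_values, bins=edges)
    q = np.linspace(0.0, 100.0, 101)
    qq = np.column_stack(
        [np.percentile(R.p_values, q), np.percentile(P.p_values, q)]
    )
    sp = np.sort(P.p_values)
    sr = np.sort(R.p_values)
    return {
        "bin_edges": edges,
        "hist_P": hist_P,
        "hist_R": hist_R,
        "qq_pairs": qq,
        "cdf_P": np.column_stack([sp, np.arange(1, len(sp) + 1) / len(sp)]),
        "cdf_R": np.column_stack([sr, np.arange(1, len(sr) + 1) / len(sr)]),
    }
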