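"""Statistical primitives used throughout the pipeline.

The two-sample log-rank test is implemented here in a vectorized batch form:
the resampling procedure evaluates thousands of group assignments against a
single survival table, so the risk-set accumulation is done once on the
time-sorted table and reused across all label vectors. The remaining
primitives (Fisher exact test, hypergeometric tail, Spearman distance,
percentile rule) delegate to scipy/numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import SurvivalTable

__all__ = [
    "TwoByTwoTable",
    "LogRankResult",
    "logrank_test",
    "batch_logrank",
    "fisher_exact",
    "hypergeometric_tail",
    "spearman_distance",
    "empirical_percentile",
]


@dataclass
class TwoByTwoTable:
    """Counts (a, b / c, d); row 1 = condition present, row 2 = absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"table entry {name}={v} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    n_events: int


def batch_logrank(
    labels: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample log-rank chi-square for many binary label vectors at once.

    Parameters
    ----------
    labels
        Boolean matrix of shape ``(B, n)``; ``True`` marks group 1.
    time, event
        Shared survival data of length ``n``.

    Returns
    -------
    (statistic, p_value)
        Arrays of length ``B``. At each distinct event time the observed
        minus expected events in group 1 accumulates, with the standard
        hypergeometric variance including the ``(n-d)/(n-1)`` tie correction;
        the statistic is ``(sum O-E)^2 / sum V`` referred to chi-square(1).
        A degenerate batch entry (one group empty, or zero variance) yields
        statistic 0, p 1.
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=bool))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n = time.shape[0]
    if labels.shape[1] != n:
        raise ValueError("labels and survival lengths differ")
    if event.sum() == 0:
        raise ValueError("no events: log-rank test undefined")

    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    L = labels[:, order].astype(float)

    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_risk = n - starts                                  # total at risk (T,)
    d = np.add.reduceat(e, starts)                       # events per time (T,)
    # group-1 at-risk counts: suffix sums of sorted labels
    n1 = np.cumsum(L[:, ::-1], axis=1)[:, ::-1][:, starts]    # (B, T)
    d1 = np.add.reduceat(L * e, starts, axis=1)               # (B, T)

    keep = d > 0
    nr = n_risk[keep].astype(float)
    dk = d[keep]
    p1 = n1[:, keep] / nr
    o_minus_e = (d1[:, keep] - dk * p1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tie = np.where(nr > 1, (nr - dk) / (nr - 1.0), 0.0)
    var = (dk * p1 * (1.0 - p1) * tie).sum(axis=1)

    stat = np.zeros(labels.shape[0])
    ok = var > 0
    stat[ok] = o_minus_e[ok] ** 2 / var[ok]
    pval = sps.chi2.sf(stat, df=1)
    pval[~ok] = 1.0
    return stat, pval


def logrank_test(groups: np.ndarray, survival: SurvivalTable) -> LogRankResult:
    """Standard two-sample log-rank test on one binary group assignment.

    ``groups`` is a boolean (or 0/1) vector aligned with ``survival``; both
    groups must be non-empty and at least one event must be observed.
    """
    g = np.asarray(groups)
    if g.dtype != bool:
        uniq = np.unique(g)
        if len(uniq) != 2:
            raise ValueError("exactly two non-empty groups required")
        g = g == uniq[1]
    if g.all() or (~g).all():
        raise ValueError("exactly two non-empty groups required")
    stat, p = batch_logrank(g[None, :], survival.time, survival.event)
    return LogRankResult(float(stat[0]), float(p[0]), survival.n_events)


def fisher_exact(
    table: TwoByTwoTable, side: str = "two_sided"
) -> tuple[float, float]:
    """Fisher exact test on a 2x2 table.

    Returns ``(odds_ratio, p_value)`` with the sample odds ratio
    ``(a*d)/(b*c)`` (infinite when ``b*c == 0`` and ``a*d > 0``). The
    two-sided p uses the probability-mass rule (sum over tables with
    hypergeometric probability at most that of the observed one), matching
    the R convention.
    """
    if side not in ("two_sided", "greater"):
        raise ValueError(f"unknown side {side!r}")
    alt = "two-sided" if side == "two_sided" else "greater"
    arr = [[table.a, table.b], [table.c, table.d]]
    res = sps.fisher_exact(arr, alternative=alt)
    if table.b * table.c == 0:
        oddsratio = np.inf if table.a * table.d > 0 else np.nan
    else:
        oddsratio = (table.a * table.d) / (table.b * table.c)
    return float(oddsratio), float(res.pvalue)


def hypergeometric_tail(
    overlap: int, draws1: int, draws2: int, universe: int
) -> float:
    """Upper tail P(X >= overlap) for X ~ Hypergeometric(universe, draws1, draws2)."""
    if not (0 <= overlap <= min(draws1, draws2) <= universe):
        raise ValueError(
            f"inconsistent arguments: overlap={overlap}, draws=({draws1},{draws2}), "
            f"universe={universe}"
        )
    return float(sps.hypergeom.sf(overlap - 1, universe, draws1, draws2))


def spearman_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Spearman rank correlation (average ranks for ties); range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(1.0 - rho)


def empirical_percentile(values: np.ndarray, q: float) -> float:
    """Order-statistic percentile with linear interpolation (inclusive rule).

    The rank is ``(n-1) * q/100`` interpolated between closest order
    statistics; fixed so that significance thresholds are reproducible.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    if not 0 <= q <= 100:
        raise ValueError("q must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))
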