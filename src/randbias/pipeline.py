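"""Orchestration of the full study design on one dataset.

Runs the bias size sweep on raw and proliferation-adjusted expression,
optionally the half-split consistency analysis and the graph
sub-classification, then re-runs the single-size bias analysis inside each
cluster (against size-matched random subsample controls) and inside clinical
label strata. Every analysis group recomputes its own empirical null on its
own survival, since the null depends on the survival distribution and group
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import (
    BiasProfile,
    BiasResult,
    bias_result_from_samples,
    null_pvalues,
    random_set_pvalues,
    run_bias_analysis,
)
from .clustering import ClusterPartition, cluster_dataset
from .consistency import ConsistencyResult, consistency_analysis
from .containers import (
    ClinicalLabels,
    ExpressionMatrix,
    SurvivalTable,
    align_expression_survival,
)
from .io import write_results
from .proliferation import (
    adjust_expression,
    derive_signature_from_anchor,
    proliferation_score,
)

logger = logging.getLogger("randbias")

__all__ = [
    "PipelineConfig",
    "ClusterBias",
    "DatasetReport",
    "bias_at_size",
    "analyze_dataset",
    "per_cluster_analysis",
    "subsample_control",
    "stratify_by_label",
    "render_report",
]


@dataclass
class PipelineConfig:
    """Shared defaults for one dataset analysis (recorded as provenance)."""

    b: int = 5000
    set_sizes: tuple[int, ...] = tuple(2**k for k in range(11))
    set_size: int = 64
    alpha: float = 0.05
    k: int | None = None
    min_cluster_size: int = 10
    seed: int = 0
    anchor_gene: str | None = None
    top_fraction: float = 0.01
    signature: list[str] | None = None
    run_consistency: bool = False
    run_clustering: bool = False
    n_splits: int = 50
    sets_per_split: int = 100
    dataset_label: str = ""


@dataclass
class ClusterBias:
    """Bias result restricted to one cluster / label / subsample group."""

    group: str
    n_samples: int
    result: BiasResult


@dataclass
class DatasetReport:
    dataset_label: str
    bias_raw: BiasProfile
    bias_adjusted: BiasProfile | None = None
    consistency: ConsistencyResult | None = None
    partition: ClusterPartition | None = None
    per_cluster: list[ClusterBias] = field(default_factory=list)
    subsample_control: list[ClusterBias] = field(default_factory=list)
    per_label: list[ClusterBias] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def bias_at_size(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    set_size: int,
    b: int,
    seed: int,
) -> BiasResult:
    """Single-size bias analysis with its own null on this group's survival."""
    expr, surv = align_expression_survival(expr, surv)
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    R = null_pvalues(surv, b, int(seeds[0]))
    P = random_set_pvalues(expr, surv, set_size, b, int(seeds[1]))
    return bias_result_from_samples(P, R)


def _resolve_signature(expr: ExpressionMatrix, config: PipelineConfig):
    from .containers import GeneList

    if config.signature:
        return GeneList(list(config.signature)), "file"
    if config.anchor_gene:
        sig = derive_signature_from_anchor(
            expr, config.anchor_gene, config.top_fraction
        )
        return sig, f"anchor:{config.anchor_gene}"
    return None, None


def analyze_dataset(
    expr: ExpressionMatrix, surv: SurvivalTable, config: PipelineConfig
) -> DatasetReport:
    """Run the configured stages on one dataset and collect a report."""
    expr, surv = align_expression_survival(expr, surv)
    ss = np.random.SeedSequence(config.seed).generate_state(6) % (2**31)
    report = DatasetReport(
        dataset_label=config.dataset_label,
        bias_raw=run_bias_analysis(
            expr, surv, config.set_sizes, config.b, int(ss[0]),
            dataset_label=config.dataset_label,
        ),
    )
    signature, sig_source = _resolve_signature(expr, config)
    if signature is not None:
        score = proliferation_score(expr, signature)
        adjusted = adjust_expression(expr, score).expression
        report.bias_adjusted = run_bias_analysis(
            adjusted, surv, config.set_sizes, config.b, int(ss[1]),
            dataset_label=config.dataset_label, adjusted=True,
        )
    if config.run_consistency:
        report.consistency = consistency_analysis(
            expr, surv, config.set_size, config.n_splits,
            config.sets_per_split, config.alpha, int(ss[2]),
        )
    if config.run_clustering:
        report.partition = cluster_dataset(expr, config.k, seed=int(ss[3]))
        report.per_cluster = per_cluster_analysis(
            expr, surv, report.partition, config.b, config.set_size,
            config.min_cluster_size, int(ss[4]),
        )
        sizes = [cb.n_samples for cb in report.per_cluster]
        report.subsample_control = subsample_control(
            expr, surv, sizes, config.b, config.set_size, int(ss[5])
        )
    report.provenance = {
        "b": config.b,
        "set_sizes": list(config.set_sizes),
        "set_size": config.set_size,
        "alpha": config.alpha,
        "k": config.k,
        "min_cluster_size": config.min_cluster_size,
        "seed": config.seed,
        "signature_source": sig_source,
        "top_fraction": config.top_fraction,
        "log_transformed": expr.log_transformed,
        "percentile_rule": "linear interpolation, inclusive",
        "n_samples": expr.n_samples,
        "n_genes": expr.n_genes,
    }
    return report


def per_cluster_analysis(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    partition: ClusterPartition,
    b: int,
    set_size: int = 64,
    min_cluster_size: int = 10,
    seed: int = 0,
) -> list[ClusterBias]:
    """Re-run the single-size bias analysis inside each sufficiently large cluster."""
    expr, surv = align_expression_survival(expr, surv)
    if partition.sample_ids != expr.sample_ids:
        raise ValueError("partition does not cover the expression samples")
    out: list[ClusterBias] = []
    ss = np.random.SeedSequence(seed).generate_state(partition.labels.max() + 1)
    for cid in range(partition.labels.max() + 1):
        idx = np.flatnonzero(partition.labels == cid)
        if len(idx) < min_cluster_size:
            logger.warning(
                "cluster %d has %d samples (< %d): skipped",
                cid, len(idx), min_cluster_size,
            )
            continue
        res = bias_at_size(
            expr.subset_samples(idx), surv.subset(idx), set_size, b,
            int(ss[cid] % (2**31)),
        )
        out.append(ClusterBias(str(cid), len(idx), res))
    if not out:
        raise ValueError(f"no cluster reaches min_cluster_size={min_cluster_size}")
    return out


def subsample_control(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    cluster_sizes: list[int],
    b: int,
    set_size: int = 64,
    seed: int = 0,
) -> list[ClusterBias]:
    """Size-matched random subsample analyses (the Fig-2B-style control)."""
    if len(cluster_sizes) == 0:
        raise ValueError("cluster_sizes must be non-empty")
    expr, surv = align_expression_survival(expr, surv)
    n = expr.n_samples
    rng = np.random.default_rng(seed)
    out: list[ClusterBias] = []
    for rep, size in enumerate(cluster_sizes):
        if size > n:
            raise ValueError(f"subsample size {size} exceeds cohort size {n}")
        idx = np.sort(rng.choice(n, size=size, replace=False))
        res = bias_at_size(
            expr.subset_samples(idx), surv.subset(idx), set_size, b,
            int(rng.integers(2**31)),
        )
        out.append(ClusterBias(f"subsample_{rep}", size, res))
    return out


def stratify_by_label(
    expr: ExpressionMatrix,
    surv: SurvivalTable,
    labels: ClinicalLabels,
    b: int,
    set_size: int = 64,
    min_group_size: int = 10,
    seed: int = 0,
) -> list[ClusterBias]:
    """Per-label restricted bias analysis (e.g. stratifying by grade)."""
    expr, surv = align_expression_survival(expr, surv)
    lab_map = dict(zip(labels.sample_ids, labels.labels))
    assigned = [lab_map.get(s) for s in expr.sample_ids]
    n_missing = sum(1 for a in assigned if a is None)
    if n_missing:
        logger.warning("%d samples without a label excluded", n_missing)
    groups = sorted({a for a in assigned if a is not None})
    out: list[ClusterBias] = []
    ss = np.random.SeedSequence(seed).generate_state(max(len(groups), 1))
    for gi, lab in enumerate(groups):
        idx = np.flatnonzero(np.asarray([a == lab for a in assigned]))
        if len(idx) < min_group_size:
            logger.warning(
                "label %r has %d samples (< %d): skipped", lab, len(idx), min_group_size
            )
            continue
        res = bias_at_size(
            expr.subset_samples(idx), surv.subset(idx), set_size, b,
            int(ss[gi] % (2**31)),
        )
        out.append(ClusterBias(str(lab), len(idx), res))
    if not out:
        raise ValueError(f"no label group reaches min_group_size={min_group_size}")
    return out


def _profile_row(profile: BiasProfile, set_size: int) -> tuple[float, float]:
    r = profile.at_size(set_size)
    return 100.0 * r.prop_signif, r.p_two_sided


def render_report(report: DatasetReport, out_dir: str | Path) -> None:
    """Write the report as numeric TSV tables plus a lossless JSON dump."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    set_size = report.provenance.get("set_size", 64)

    row: dict = {"dataset": report.dataset_label}
    try:
        row["signif_pct"], row["p_value"] = _profile_row(report.bias_raw, set_size)
    except KeyError:
        r0 = report.bias_raw.results[-1]
        row["signif_pct"], row["p_value"] = 100.0 * r0.prop_signif, r0.p_two_sided
    if report.bias_adjusted is not None:
        row["adjusted_pct"], row["adjusted_p"] = _profile_row(
            report.bias_adjusted, set_size
        )
    pd.DataFrame([row]).to_csv(out / "table1.tsv", sep="\t", index=False)

    prof_rows = []
    for profile in (report.bias_raw, report.bias_adjusted):
        if profile is None:
            continue
        for r in profile.results:
            prof_rows.append(
                {
                    "dataset": report.dataset_label,
                    "adjusted": profile.adjusted,
                    "set_size": r.set_size,
                    "prop_signif": r.prop_signif,
                    "threshold_r": r.threshold_r,
                    "z": r.z,
                    "p_two_sided": r.p_two_sided,
                    "direction": r.direction,
                }
            )
    pd.DataFrame(prof_rows).to_csv(out / "bias_profile.tsv", sep="\t", index=False)

    if report.consistency is not None:
        c = report.consistency
        pd.DataFrame(
            [
                {
                    "dataset": report.dataset_label,
                    "signif_pct": 100.0 * c.per_half_signif_prop,
                    "repeat_pct": 100.0 * c.repeat_prop,
                    "p_value": c.fisher_p,
                    "odds_ratio": c.odds_ratio,
                }
            ]
        ).to_csv(out / "table2.tsv", sep="\t", index=False)

    def _group_rows(entries: list[ClusterBias], kind: str) -> list[dict]:
        return [
            {
                "dataset": report.dataset_label,
                "kind": kind,
                "group": cb.group,
                "n_samples": cb.n_samples,
                "prop_signif": cb.result.prop_signif,
                "p_two_sided": cb.result.p_two_sided,
                "direction": cb.result.direction,
            }
            for cb in entries
        ]

    group_rows = _group_rows(report.per_cluster, "cluster") + _group_rows(
        report.subsample_control, "subsample"
    )
    if group_rows:
        pd.DataFrame(group_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if report.per_label:
        pd.DataFrame(_group_rows(report.per_label, "label")).to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
    if report.partition is not None:
        write_results(report.partition, out / "partition.tsv")
    write_results(report, out / "report.json")
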