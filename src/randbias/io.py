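"""Readers and writers for the pipeline's external file formats.

Expression matrices are tab-separated with gene ids in the first column and
sample ids in the header (TCGA level-3 RSEM layout). Survival tables are TSV
with columns ``sample_id``, ``time``, ``event``. Result records serialize to
JSON (nested, lossless round-trip) or TSV (flat tables).
"""

from __future__ import annotations

import dataclasses
import json

from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .containers import ClinicalLabels, ExpressionMatrix, GeneList, SurvivalTable

__all__ = [
    "read_expression",
    "read_survival",
    "read_gene_list",
    "read_clinical_labels",
    "write_expression",
    "write_survival",
    "write_results",
    "read_results",
]


def read_expression(
    path: str | Path, log_transform: bool = True, already_log: bool = False
) -> ExpressionMatrix:
    """Read a genes x samples TSV, optionally applying log2(x+1).

    The transform defaults to on because downstream correlation and PCA are
    variance-sensitive on RSEM-scale values; the flag used is recorded on the
    returned matrix for provenance. ``already_log=True`` declares the file to
    be on a log-like scale already (negative values allowed, no transform
    applied).
    """
    if already_log and log_transform:
        raise ValueError("already_log and log_transform are mutually exclusive")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    try:
        values = df.astype(float).to_numpy()
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, raw in enumerate(df[col]):
                try:
                    float(raw)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene_ids[i]!r}, "
                        f"sample {col!r}: {raw!r}"
                    ) from None
        raise
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
        raise ValueError(
            f"missing values for genes: {[gene_ids[i] for i in bad[:10]]}"
        )
    if log_transform:
        if (values < 0).any():
            raise ValueError("negative values: cannot apply log2(x+1)")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(
        values,
        gene_ids,
        [str(c) for c in df.columns],
        log_transformed=log_transform or already_log,
    )


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a TSV with columns sample_id, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return SurvivalTable(
        [str(s) for s in df["sample_id"]],
        df["time"].to_numpy(float),
        df["event"].to_numpy(float),
    )


def read_gene_list(path: str | Path) -> GeneList:
    """Read one gene symbol per line; blank lines ignored, duplicates warned."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    symbols = [ln for ln in lines if ln]
    if not symbols:
        raise ValueError(f"gene list file {path} is empty")
    return GeneList(symbols)


def read_clinical_labels(path: str | Path, label_column: str = "label") -> ClinicalLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or label_column not in df.columns:
        raise ValueError(f"labels table needs columns sample_id and {label_column!r}")
    return ClinicalLabels(list(df["sample_id"]), list(df[label_column]))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic result serialization


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            "data": {
                f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


def _registry() -> dict[str, type]:
    # late imports: io must not depend on analysis modules at import time
    from . import bias, clustering, consistency, proliferation
    from .pipeline import ClusterBias, DatasetReport

    types = [
        bias.PValueSample,
        bias.BiasResult,
        bias.BiasProfile,
        consistency.ConsistencyResult,
        clustering.ClusterPartition,
        proliferation.ProliferationScore,
        ClusterBias,
        DatasetReport,
    ]
    return {t.__name__: t for t in types}


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict) and "__type__" in obj:
        cls = _registry()[obj["__type__"]]
        kwargs = {k: _from_jsonable(v) for k, v in obj["data"].items()}
        return cls(**kwargs)
    if isinstance(obj, list):
        return [_from_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _from_jsonable(v) for k, v in obj.items()}
    return obj


def _flat_frame(result: Any) -> pd.DataFrame:
    """Flatten a result record into a table for TSV output."""
    from .bias import BiasProfile, BiasResult
    from .clustering import ClusterPartition

    if isinstance(result, BiasProfile):
        rows = [dataclasses.asdict(r) for r in result.results]
        df = pd.DataFrame(rows)
        df.insert(0, "dataset_label", result.dataset_label)
        df.insert(1, "adjusted", result.adjusted)
        return df
    if isinstance(result, ClusterPartition):
        return pd.DataFrame(
            {"sample_id": result.sample_ids, "cluster": list(result.labels)}
        )
    if isinstance(result, BiasResult):
        return pd.DataFrame([dataclasses.asdict(result)])
    if dataclasses.is_dataclass(result):
        d = {
            k: v
            for k, v in dataclasses.asdict(result).items()
            if np.isscalar(v) or v is None
        }
        return pd.DataFrame([d])
    raise TypeError(f"cannot flatten {type(result).__name__} to TSV")


def write_results(result: Any, path: str | Path, format: str | None = None) -> None:
    """Write a result record as JSON (lossless) or TSV (flat).

    ``format`` defaults from the file extension; JSON output round-trips
    through :func:`read_results` field-for-field.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        path.write_text(json.dumps(_to_jsonable(result), indent=1))
    elif fmt == "tsv":
        _flat_frame(result).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_results(path: str | Path) -> Any:
    """Re-hydrate a JSON result written by :func:`write_results`."""
    return _from_jsonable(json.loads(Path(path).read_text()))
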