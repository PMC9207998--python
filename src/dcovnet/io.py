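"""Delimited-text readers and writers.

Time series travel as TSV (first column ``node``, remaining columns
samples) with a JSON sidecar holding ``dt``, ``kind`` and any provenance;
connectivity and SC matrices as labeled square TSVs; edge significances as
long-format TSVs (source, sink, empirical, null_mean, null_sd, p).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, EdgeSignificance, SurrogateSC, TimeSeriesMatrix

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_matrix", "read_matrix",
    "write_connectivity", "read_connectivity",
    "write_significance", "write_sc",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: TimeSeriesMatrix, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.values, index=pd.Index(ts.labels, name="node"))
    df.to_csv(path, sep="\t", float_format="%.10g")
    meta = {"dt": ts.dt, "kind": ts.kind}
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_timeseries(path, dt: float | None = None, kind: str | None = None) -> TimeSeriesMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    dt = dt if dt is not None else float(meta.get("dt", 1.0))
    kind = kind if kind is not None else str(meta.get("kind", "neural"))
    return TimeSeriesMatrix(df.to_numpy(dtype=float), [str(x) for x in df.index], dt, kind)


def write_matrix(values: np.ndarray, labels: list[str], path) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        Path(path), sep="\t", float_format="%.10g")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(x) for x in df.index]


def write_connectivity(cm: ConnectivityMatrix, path) -> None:
    path = Path(path)
    write_matrix(cm.values, cm.labels, path)
    meta = {"method": cm.method, "directed": cm.directed, "convention": cm.convention}
    meta.update({k: v for k, v in cm.meta.items()
                 if isinstance(v, (int, float, str, bool))})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    values, labels = read_matrix(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return ConnectivityMatrix(values, labels, meta.get("method", "cov"),
                              bool(meta.get("directed", False)),
                              meta.get("convention", "row=sink,col=source"))


def write_significance(sig: EdgeSignificance, path) -> None:
    rows = []
    n = len(sig.labels)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rows.append({
                "sink": sig.labels[i],
                "source": sig.labels[j],
                "empirical": sig.empirical[i, j],
                "null_mean": sig.null_mean[i, j],
                "null_sd": sig.null_sd[i, j],
                "p": sig.p_values[i, j],
            })
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def write_sc(sc: SurrogateSC, path) -> None:
    write_matrix(sc.weights, sc.labels, path)
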