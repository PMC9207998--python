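"""FC-SC correspondence via structural-connectivity strength (SCS).

Significant functional edges act as a boolean mask on the structural
matrix; the masked structural strengths, pooled over subjects, form the SCS
set, and their mean (ASCS) scores how preferentially an FC method selects
anatomically strong connections.  The diagonal is always excluded
(self-terms are not connections).  Directed FC masks are looked up at the
same matrix positions of the SC matrix (both in the sink-row orientation);
undirected FC masks are symmetric, so both orientations of every undirected
edge contribute one entry each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BinaryNetwork, EdgeSignificance, SCSResult, SurrogateSC
from .edge_significance import binarize

__all__ = ["load_structural", "scs_values", "ascs_curve"]


def load_structural(
    path,
    labels: list[str],
    region_map: dict[str, list[str]] | None = None,
) -> SurrogateSC:
    """Read a labeled square SC matrix (TSV) and align it to FC node order.

    ``region_map`` maps each FC node to one or more atlas regions of the
    file; a node spanning several regions gets the mean strength over all
    its region pairs.  Without a map, labels must match the file's labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if region_map is None:
        region_map = {lab: [lab] for lab in labels}
    missing = sorted(
        {r for lab in labels for r in region_map.get(lab, [])
         if r not in df.index or r not in df.columns}
        | {lab for lab in labels if lab not in region_map}
    )
    if missing:
        raise KeyError(f"labels/regions not found in SC file: {missing}")
    n = len(labels)
    out = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            block = df.loc[region_map[li], region_map[lj]].to_numpy(dtype=float)
            out[i, j] = float(block.mean())
    symmetric = bool(np.allclose(out, out.T))
    return SurrogateSC(out, list(labels), symmetric=symmetric,
                       convention="generic" if not _is_mouse_scale(out) else "mouse")


def _is_mouse_scale(w: np.ndarray) -> bool:
    return bool(np.all(np.isin(np.unique(w), np.arange(1, 8))) and np.all(np.diag(w) == 7))


def scs_values(
    binaries: list[BinaryNetwork],
    sc: SurrogateSC,
    method: str = "",
    threshold: float = float("nan"),
) -> SCSResult:
    """Pool SC strengths at significant off-diagonal FC positions.

    Each subject's binary network contributes the SC entries at its true
    off-diagonal positions; repeats across subjects keep their multiplicity.
    An empty pooled set yields ``ascs = NaN`` with ``empty = True``.
    """
    pooled: list[float] = []
    for net in binaries:
        if net.labels != sc.labels:
            raise ValueError("binary network labels do not match the SC labels")
        mask = net.adjacency.copy()
        np.fill_diagonal(mask, False)
        pooled.extend(sc.weights[mask].tolist())
    return SCSResult(np.asarray(pooled, dtype=float), method=method,
                     threshold=threshold, n_subjects=len(binaries))


def ascs_curve(
    sigs: list[EdgeSignificance],
    sc: SurrogateSC,
    thresholds: list[float],
) -> list[SCSResult]:
    """One pooled SCS result per binarization threshold (given descending).

    Decreasing thresholds select nested, shrinking edge sets, tracing an
    asymptotic picture of how strongly the surviving edges are anatomically
    connected.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be in descending order")
    method = sigs[0].method if sigs else ""
    results = []
    for thr in thresholds:
        nets = [binarize(s, thr) for s in sigs]
        results.append(scs_values(nets, sc, method=method, threshold=thr))
    return results
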