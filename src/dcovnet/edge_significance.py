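"""Edge significance by autoregressive bootstrap.

The null hypothesis for every edge is that all node traces were generated
independently.  Null data are drawn by fitting a separate AR model to each
node (order chosen by a conservative BIC rule) and simulating each node's
model independently, which preserves every node's power spectrum while
destroying all cross-dependencies.  Each edge's null distribution of FC
values is summarised by a Gaussian fit, giving a two-sided p-value for the
empirical value; no multiple-comparison correction is applied — different
significance levels serve as binarization thresholds instead.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, Iterator

import numpy as np
from scipy.stats import norm

from .containers import (
    ARModel,
    BinaryNetwork,
    ConnectivityMatrix,
    EdgeSignificance,
    SINK_SOURCE,
    StabilityError,
    SYMMETRIC_METHODS,
    TimeSeriesMatrix,
)

__all__ = [
    "fit_ar",
    "generate_null",
    "edge_pvalues",
    "binarize",
    "match_sparsity",
    "significance_pipeline",
    "DEFAULT_THRESHOLDS",
]

#: significance levels used for binarization when none are given
DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001)

#: samples discarded at the start of every surrogate draw
_SURROGATE_BURN_IN = 500

#: a higher AR order must lower BIC by more than this to be accepted
_BIC_MARGIN = 2.0


def _fit_single_ar(x: np.ndarray, max_order: int) -> tuple[int, np.ndarray, float]:
    """Incremental BIC order selection with conditional least squares.

    All candidate orders are scored on the common sample ``t >= max_order``
    so their BICs are comparable.  Order ``q + 1`` replaces ``q`` only when
    it lowers BIC by more than 2; the first rejection stops the search.
    """
    T = x.size
    t_eff = T - max_order
    y = x[max_order:]

    def fit(q: int) -> tuple[np.ndarray, float]:
        if q == 0:
            rss = float(np.sum(y ** 2))
            return np.empty(0), rss
        design = np.column_stack([x[max_order - k : T - k] for k in range(1, q + 1)])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ coef) ** 2))
        return coef, rss

    def bic(q: int, rss: float) -> float:
        return t_eff * np.log(max(rss, 1e-300) / t_eff) + q * np.log(t_eff)

    coef, rss = fit(0)
    best = (0, coef, rss, bic(0, rss))
    for q in range(1, max_order + 1):
        coef, rss = fit(q)
        b = bic(q, rss)
        if b < best[3] - _BIC_MARGIN:
            best = (q, coef, rss, b)
        else:
            break
    return best[0], best[1], np.sqrt(best[2] / t_eff)


def fit_ar(ts: TimeSeriesMatrix, max_order: int = 20) -> list[ARModel]:
    """Per-node AR models fitted on the centred traces.

    Orders are accepted incrementally while BIC improves by more than 2.
    If the selected model is nonstationary the order is reduced until a
    stationary fit is found; an all-orders-nonstationary node raises
    :class:`StabilityError`.
    """
    if ts.n_samples <= 3 * max_order:
        raise ValueError("need T > 3 * max_order samples")
    models = []
    for row, label in zip(ts.values, ts.labels):
        mean = float(np.mean(row))
        x = row - mean
        order, coef, sd = _fit_single_ar(x, max_order)
        while True:
            try:
                models.append(ARModel(order, coef[:order], sd, label, mean=mean))
                break
            except ValueError:
                if order == 0:
                    raise StabilityError(f"no stationary AR fit for node {label!r}")
                order -= 1
                coef2, rss = _refit(x, order, max_order)
                coef, sd = coef2, np.sqrt(rss / (x.size - max_order))
    return models


def _refit(x: np.ndarray, q: int, max_order: int) -> tuple[np.ndarray, float]:
    T = x.size
    y = x[max_order:]
    if q == 0:
        return np.empty(0), float(np.sum(y ** 2))
    design = np.column_stack([x[max_order - k : T - k] for k in range(1, q + 1)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    return coef, float(np.sum((y - design @ coef) ** 2))


def generate_null(
    models: list[ARModel],
    T: int,
    n_surrogates: int = 1000,
    seed: int = 0,
    dt: float = 1.0,
) -> Iterator[TimeSeriesMatrix]:
    """Yield surrogate time-series matrices drawn node-wise independently.

    Each surrogate simulates every node from its own AR model with fresh
    Gaussian innovations, discarding a 500-sample burn-in, so node spectra
    are preserved while all cross-node dependencies vanish.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    labels = [m.node_label for m in models]
    total = T + _SURROGATE_BURN_IN
    for _ in range(n_surrogates):
        out = np.empty((len(models), T))
        for i, m in enumerate(models):
            eps = m.noise_sd * rng.standard_normal(total)
            if m.order == 0:
                sim = eps
            else:
                sim = lfilter([1.0], np.concatenate([[1.0], -m.coefficients]), eps)
            out[i] = m.mean + sim[_SURROGATE_BURN_IN:]
        yield TimeSeriesMatrix(out, labels, dt, kind="surrogate")


def edge_pvalues(
    empirical: ConnectivityMatrix,
    null_fcs: Iterable[ConnectivityMatrix],
) -> EdgeSignificance:
    """Gaussian-null two-sided p-values per edge.

    The null mean and standard deviation of each edge are accumulated over
    the surrogate FC matrices (at least 50 required); then
    ``p = 2 * Phi(-|x - mu| / sigma)``.  Edges whose null never varies get
    p = 1 when the empirical value equals the null mean and p = 0
    otherwise, with a warning.
    """
    count = 0
    mean = None
    m2 = None
    for fc in null_fcs:
        if fc.method != empirical.method:
            raise ValueError(
                f"surrogate method {fc.method!r} does not match empirical {empirical.method!r}"
            )
        v = fc.values
        if mean is None:
            mean = np.zeros_like(v)
            m2 = np.zeros_like(v)
        count += 1
        delta = v - mean
        mean += delta / count
        m2 += delta * (v - mean)
    if count < 50:
        raise ValueError(f"need at least 50 null matrices, got {count}")
    sd = np.sqrt(m2 / (count - 1))

    x = empirical.values
    p = np.ones_like(x)
    varying = sd > 0
    p[varying] = 2.0 * norm.sf(np.abs(x[varying] - mean[varying]) / sd[varying])
    degenerate = ~varying
    if np.any(degenerate & (x != mean)):
        warnings.warn("some edges have zero null variance; assigning p = 0 there",
                      RuntimeWarning)
    p[degenerate & (x != mean)] = 0.0
    p[degenerate & (x == mean)] = 1.0
    return EdgeSignificance(
        empirical=x.copy(), null_mean=mean, null_sd=sd, p_values=p,
        n_surrogates=count, method=empirical.method, labels=list(empirical.labels),
        directed=empirical.directed,
    )


def binarize(sig: EdgeSignificance, threshold: float) -> BinaryNetwork:
    """Adjacency true where ``p < threshold``; diagonal forced off.

    For symmetric (undirected) estimators the adjacency is symmetrised by
    union so the result is a valid undirected network.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    adj = sig.p_values < threshold
    np.fill_diagonal(adj, False)
    directed = sig.directed and sig.method not in SYMMETRIC_METHODS
    if not directed:
        adj = adj | adj.T
    return BinaryNetwork(adj, directed=directed, threshold=threshold,
                         labels=list(sig.labels), convention=SINK_SOURCE)


def _edge_ranking(sig: EdgeSignificance) -> list[tuple[int, int]]:
    """Off-diagonal edges from most to least significant.

    Smallest p first; ties broken by larger |empirical| then row-major
    position.
    """
    n = len(sig.labels)
    edges = [(i, j) for i in range(n) for j in range(n) if i != j]
    edges.sort(key=lambda e: (sig.p_values[e], -abs(sig.empirical[e]), e[0], e[1]))
    return edges


def match_sparsity(
    sig_a: EdgeSignificance,
    sig_b: EdgeSignificance,
    k: int,
) -> tuple[BinaryNetwork, BinaryNetwork]:
    """Binary networks keeping exactly the k most significant edges of each."""
    nets = []
    for sig in (sig_a, sig_b):
        n = len(sig.labels)
        if not 0 <= k <= n * (n - 1):
            raise ValueError("k must lie in [0, N(N-1)]")
        adj = np.zeros((n, n), dtype=bool)
        for (i, j) in _edge_ranking(sig)[:k]:
            adj[i, j] = True
        nets.append(BinaryNetwork(adj, directed=True, threshold=float("nan"),
                                  labels=list(sig.labels), convention=SINK_SOURCE))
    return nets[0], nets[1]


def significance_pipeline(
    z: TimeSeriesMatrix,
    estimator: Callable[[TimeSeriesMatrix], ConnectivityMatrix],
    n_surrogates: int = 1000,
    seed: int = 0,
    max_order: int = 20,
) -> EdgeSignificance:
    """Fit AR nulls to ``z``, push surrogates through ``estimator`` and
    return edge significances.  Deterministic given (data, seed)."""
    empirical = estimator(z)
    models = fit_ar(z, max_order=max_order)
    nulls = generate_null(models, z.n_samples, n_surrogates, seed=seed, dt=z.dt)
    return edge_pvalues(empirical, (estimator(s) for s in nulls))
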