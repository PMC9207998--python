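"""Core in-memory containers shared across the pipeline.

All containers are plain dataclasses around numpy arrays.  Directed
connectivity matrices follow a single convention throughout the package:
``row = sink, column = source`` — entry ``(i, j)`` is the influence of node
``j`` on node ``i``.  Binary networks record which convention their adjacency
uses so that graph-theoretic code can normalise to the usual
``a_ij = edge i -> j`` orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: canonical orientation tag for directed FC matrices
SINK_SOURCE = "row=sink,col=source"
#: graph-theory orientation: a_ij = 1 means an edge from i to j
SOURCE_SINK = "row=source,col=sink"

TS_KINDS = ("neural", "bold", "reconstructed", "derivative", "surrogate")


class StabilityError(RuntimeError):
    """A simulated trajectory or fitted model left the stable regime."""


class IllConditionedError(np.linalg.LinAlgError):
    """A regression design was too ill-conditioned to trust."""


@dataclass
class TimeSeriesMatrix:
    """N node traces over T samples with labels and a sampling interval.

    Parameters
    ----------
    values : (N, T) float array
    labels : node names, unique, length N
    dt : sampling interval in seconds
    kind : one of ``neural``, ``bold``, ``reconstructed``, ``derivative``,
        ``surrogate``
    """

    values: np.ndarray
    labels: list[str]
    dt: float
    kind: str = "neural"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (nodes x time) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least T >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count does not match node count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("node labels must be unique")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.kind not in TS_KINDS:
            raise ValueError(f"kind must be one of {TS_KINDS}")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "TimeSeriesMatrix":
        return TimeSeriesMatrix(values, list(self.labels), self.dt, kind or self.kind)


FC_METHODS = ("cov", "pcov", "l1reg", "l2reg", "cgranger", "dcov_c", "dcov_p", "dcov_s")
SYMMETRIC_METHODS = ("cov", "pcov", "l1reg", "l2reg")


@dataclass
class ConnectivityMatrix:
    """An N x N functional-connectivity estimate with a method tag."""

    values: np.ndarray
    labels: list[str]
    method: str
    directed: bool
    convention: str = SINK_SOURCE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("connectivity matrix must be square and match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("connectivity matrix contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class GroundTruthNetwork:
    """Stable sparse directed weight matrix used to drive simulations.

    ``weights[i, j]`` is the influence of node j on node i (sink-row
    convention, matching the differential-covariance orientation).
    """

    weights: np.ndarray
    labels: list[str]
    density: float
    seed: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square and match labels")
        if np.any(np.diag(self.weights) >= 0):
            raise ValueError("diagonal (self-decay) entries must be strictly negative")
        if np.max(np.linalg.eigvals(self.weights).real) >= 0:
            raise ValueError("network is not stable (spectral abscissa >= 0)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def support(self) -> np.ndarray:
        """Boolean off-diagonal support of the coupling weights."""
        s = self.weights != 0
        np.fill_diagonal(s, False)
        return s


@dataclass
class SurrogateSC:
    """Structural-connectivity matrix on either an ordinal 1..7 scale
    (axonal-tracing convention) or a nonnegative continuous scale
    (diffusion-imaging convention)."""

    weights: np.ndarray
    labels: list[str]
    symmetric: bool
    convention: str = "mouse"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("SC matrix must be square and match labels")
        if self.convention == "mouse":
            vals = np.unique(self.weights)
            if not np.all(np.isin(vals, np.arange(1, 8))):
                raise ValueError("mouse-convention entries must lie in {1..7}")
            if not np.all(np.diag(self.weights) == 7):
                raise ValueError("mouse-convention diagonal must equal 7")
        if self.symmetric and not np.allclose(self.weights, self.weights.T):
            raise ValueError("matrix marked symmetric is not")


@dataclass
class BehaviorTable:
    """Subjects x measures table with NaN as the missing marker."""

    subjects: list[str]
    measures: np.ndarray
    measure_names: list[str]
    confound_names: list[str]

    def __post_init__(self) -> None:
        self.measures = np.asarray(self.measures, dtype=float)
        if self.measures.shape != (len(self.subjects), len(self.measure_names)):
            raise ValueError("measures must be subjects x measure_names")
        unknown = set(self.confound_names) - set(self.measure_names)
        if unknown:
            raise ValueError(f"confounds not among measures: {sorted(unknown)}")

    def missing_counts(self) -> dict[str, int]:
        nan = np.isnan(self.measures).sum(axis=0)
        return dict(zip(self.measure_names, (int(x) for x in nan)))

    def column(self, name: str) -> np.ndarray:
        return self.measures[:, self.measure_names.index(name)]

    def confound_matrix(self) -> np.ndarray:
        idx = [self.measure_names.index(c) for c in self.confound_names]
        return self.measures[:, idx]


@dataclass
class BalloonParams:
    """Biophysical parameters of the haemodynamic (Balloon) model.

    Units: ``tau`` s (venous transit time), ``kappa`` and ``gamma`` 1/s
    (signal decay / flow-dependent elimination), ``alpha`` dimensionless
    (Grubb exponent), ``rho`` dimensionless (resting oxygen extraction),
    ``eta`` dimensionless (neural efficacy), ``V0`` dimensionless (resting
    venous volume fraction), ``epsilon`` dimensionless (intra/extravascular
    signal ratio), ``r0`` 1/s (intravascular relaxation slope), ``TE`` s
    (echo time) and ``B`` Tesla (field strength).  ``theta0`` (1/s), the
    frequency offset at the outer surface of magnetised vessels, scales
    linearly with field strength and defaults to ``40.3 * B / 1.5``.

    ``TE`` and ``B`` are acquisition properties and must always be supplied;
    :meth:`hcp` and :meth:`mouse` provide the two dataset presets.
    """

    TE: float
    B: float
    tau: float = 0.98
    epsilon: float = 0.5
    alpha: float = 0.32
    kappa: float = 0.65
    gamma: float = 0.41
    rho: float = 0.34
    eta: float = 0.02
    V0: float = 0.02
    r0: float = 25.0
    theta0: float | None = None

    def __post_init__(self) -> None:
        if self.theta0 is None:
            self.theta0 = 40.3 * self.B / 1.5
        for name in ("TE", "B", "tau", "epsilon", "alpha", "kappa", "gamma",
                     "rho", "eta", "V0", "r0", "theta0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha (Grubb exponent) must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho (resting oxygen extraction) must lie in (0, 1)")

    @classmethod
    def hcp(cls, **overrides) -> "BalloonParams":
        """3-T human acquisition preset (TE = 33.1 ms)."""
        kw = dict(TE=0.0331, B=3.0)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def mouse(cls, **overrides) -> "BalloonParams":
        """9.4-T mouse acquisition preset (TE = 12 ms)."""
        kw = dict(TE=0.012, B=9.4)
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("TE", "B", "tau", "epsilon", "alpha", "kappa", "gamma",
                 "rho", "eta", "V0", "r0", "theta0")}

    @classmethod
    def from_dict(cls, d: dict) -> "BalloonParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass
class ReconstructionCoefficients:
    """Coefficients of the linearised Balloon-model inversion.

    ``z = p4 y'''' + p3 y''' + p2 y'' + p1 y' + p0 y`` reconstructs a
    surrogate neural signal which, in the linear regime, equals
    ``q1 V' + q0 V`` up to numerical error.  ``k1..k3`` parameterise the
    BOLD readout ``y = V0 (k1 (1-q) + k2 (1-q/v) + k3 (1-v))``.
    """

    p: np.ndarray  # p0..p4
    q: np.ndarray  # q0, q1
    k: np.ndarray  # k1, k2, k3

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.p.shape != (5,) or self.q.shape != (2,) or self.k.shape != (3,):
            raise ValueError("expected p0..p4, q0..q1, k1..k3")


@dataclass
class SparseLatentConfig:
    """Configuration of the sparse + low-rank split of the partial dCov.

    ``alpha_penalty`` weights the L1 term of ``min a*||S||_1 + ||L||_*``
    subject to ``S + L = M``; ``None`` selects ``1/sqrt(N)`` at solve time
    (``"1/N"`` is also accepted).
    """

    alpha_penalty: float | str | None = None
    tol: float = 1e-7
    max_iter: int = 500

    def resolve_alpha(self, n: int) -> float:
        if self.alpha_penalty is None:
            return 1.0 / math.sqrt(n)
        if isinstance(self.alpha_penalty, str):
            if self.alpha_penalty.replace(" ", "") in ("1/N", "1/n"):
                return 1.0 / n
            raise ValueError(f"unrecognised alpha_penalty {self.alpha_penalty!r}")
        if not self.alpha_penalty > 0:
            raise ValueError("alpha_penalty must be positive")
        return float(self.alpha_penalty)


@dataclass
class ARModel:
    """Autoregressive model of one node's trace, fitted on the centred
    series (the process mean is stored separately)."""

    order: int
    coefficients: np.ndarray
    noise_sd: float
    node_label: str
    mean: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        if self.coefficients.shape != (self.order,):
            raise ValueError("coefficient count must equal the model order")
        if self.order > 0 and self.spectral_radius() >= 1:
            raise ValueError("AR model is not stationary")

    def spectral_radius(self) -> float:
        if self.order == 0:
            return 0.0
        companion = np.zeros((self.order, self.order))
        companion[0] = self.coefficients
        if self.order > 1:
            companion[np.arange(1, self.order), np.arange(self.order - 1)] = 1.0
        return float(np.max(np.abs(np.linalg.eigvals(companion))))

    def simulate(self, innovations: np.ndarray, history: np.ndarray | None = None) -> np.ndarray:
        """Run the recursion forward over the given innovation sequence.

        ``history`` supplies the last ``order`` centred samples (most recent
        last); zeros when omitted.  With zero innovations this is the
        noiseless impulse-response extension of the model.
        """
        from scipy.signal import lfilter

        innovations = np.asarray(innovations, dtype=float)
        if self.order == 0:
            return self.mean + innovations
        a = np.concatenate([[1.0], -self.coefficients])
        if history is None:
            zi = None
            out = lfilter([1.0], a, innovations)
        else:
            hist = np.asarray(history, dtype=float)[-self.order:] - self.mean
            from scipy.signal import lfiltic
            zi = lfiltic([1.0], a, hist[::-1])
            out, _ = lfilter([1.0], a, innovations, zi=zi)
        return self.mean + out


@dataclass
class EdgeSignificance:
    """Per-edge Gaussian null fit and two-sided p-values."""

    empirical: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    p_values: np.ndarray
    n_surrogates: int
    method: str
    labels: list[str]
    directed: bool = True

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("empirical", "null_mean", "null_sd", "p_values"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be N x N")
            setattr(self, name, arr)
        if np.any(self.p_values < 0) or np.any(self.p_values > 1):
            raise ValueError("p-values must lie in [0, 1]")


@dataclass
class BinaryNetwork:
    """Thresholded (binary) network.

    ``convention`` records the orientation of ``adjacency`` for directed
    networks: FC-derived networks keep the sink-row orientation, while graph
    analysis normalises to ``a_ij = edge i -> j``.
    """

    adjacency: np.ndarray
    directed: bool
    threshold: float
    labels: list[str]
    convention: str = SINK_SOURCE

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be N x N")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("diagonal must be False")
        if not self.directed and not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("undirected adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Directed edge count (each undirected edge counts twice)."""
        return int(self.adjacency.sum())

    def graph_adjacency(self) -> np.ndarray:
        """Adjacency in the ``a_ij = edge i -> j`` orientation."""
        if self.directed and self.convention == SINK_SOURCE:
            return self.adjacency.T.copy()
        return self.adjacency.copy()


@dataclass
class SCSResult:
    """Structural strengths of the selected functional edges and their mean."""

    values: np.ndarray
    method: str
    threshold: float
    n_subjects: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_edges(self) -> int:
        return int(self.values.size)

    @property
    def ascs(self) -> float:
        """Mean structural strength; NaN when no edge was selected."""
        if self.values.size == 0:
            return float("nan")
        return float(np.mean(self.values))

    @property
    def empty(self) -> bool:
        return self.values.size == 0


@dataclass
class TopologyReport:
    """All scalar and per-node topological measures of one binary network."""

    out_degree: np.ndarray
    in_degree: np.ndarray
    distances: np.ndarray
    triangles: np.ndarray
    global_efficiency: float
    local_efficiency: float
    clustering: float
    transitivity: float
    modularity: float
    partition: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "out_degree": [int(x) for x in self.out_degree],
            "in_degree": [int(x) for x in self.in_degree],
            "distances": [[None if math.isinf(d) else float(d) for d in row]
                          for row in self.distances],
            "triangles": [float(x) for x in self.triangles],
            "global_efficiency": float(self.global_efficiency),
            "local_efficiency": float(self.local_efficiency),
            "clustering": float(self.clustering),
            "transitivity": float(self.transitivity),
            "modularity": float(self.modularity),
            "partition": dict(self.partition),
        }


@dataclass
class BehaviorCorrelation:
    """Correlation of residual network efficiency with one behavioral measure."""

    measure_name: str
    r: float
    p: float
    n: int
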