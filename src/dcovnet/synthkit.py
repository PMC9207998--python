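"""Synthetic ground truth: networks, neural dynamics, haemodynamics, SC and
behavior surrogates.

Every stage of the connectivity pipeline can be exercised end-to-end on data
produced here, with the generating network known exactly:

* :func:`generate_network` draws a stable sparse directed linear system;
* :func:`simulate_neural` integrates the Ornstein-Uhlenbeck-type dynamics
  ``dV/dt = W V + noise`` (Euler-Maruyama);
* :func:`balloon_forward` pushes neural traces through the four-state
  Balloon-Windkessel haemodynamic model (nonlinear, or its linearisation)
  and :func:`downsample` resamples to a repetition time;
* :func:`surrogate_sc` quantises the generating weights into a
  structural-connectivity surrogate (ordinal tracing scale or symmetric
  diffusion-imaging scale);
* :func:`surrogate_behavior` builds a subject table with one measure
  linearly coupled to a network statistic plus confounds and noise.

All generators are pure functions of their arguments and an explicit seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata

from .containers import (
    BalloonParams,
    BehaviorTable,
    GroundTruthNetwork,
    StabilityError,
    SurrogateSC,
    TimeSeriesMatrix,
)
from .hemodynamics import balloon_coefficients, flow_extraction_slope

__all__ = [
    "generate_network",
    "simulate_neural",
    "balloon_forward",
    "downsample",
    "surrogate_sc",
    "surrogate_behavior",
    "bandlimited_signal",
    "DEFAULT_CONFOUND_NAMES",
]


def _node_labels(n: int) -> list[str]:
    return [f"node{i}" for i in range(n)]


def generate_network(
    n_nodes: int,
    density: float,
    self_decay: float = 1.0,
    seed: int = 0,
    max_attempts: int = 40,
) -> GroundTruthNetwork:
    """Draw a stable sparse directed weight matrix.

    Off-diagonal support is chosen uniformly at random so that exactly
    ``round(density * N * (N - 1))`` couplings are nonzero; weights have
    random sign and magnitude.  The diagonal is ``-self_decay`` and the
    coupling block is rescaled (a bounded number of times) until the
    spectral abscissa is negative.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    if not self_decay > 0:
        raise ValueError("self_decay must be positive")
    rng = np.random.default_rng(seed)
    n_off = n_nodes * (n_nodes - 1)
    n_edges = int(round(density * n_off))

    coupling = np.zeros((n_nodes, n_nodes))
    if n_edges > 0:
        off_positions = [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
        chosen = rng.choice(n_off, size=n_edges, replace=False)
        # couplings at ~half the decay rate: strong enough that indirect
        # correlations (chain/confounder propagation) are material, weak
        # enough that trajectories stay comfortably stable
        scale = 0.75 * self_decay / math.sqrt(max(1.0, n_nodes * density))
        for idx in chosen:
            i, j = off_positions[idx]
            coupling[i, j] = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * scale

    for _ in range(max_attempts):
        weights = coupling.copy()
        np.fill_diagonal(weights, -self_decay)
        if np.max(np.linalg.eigvals(weights).real) < 0:
            return GroundTruthNetwork(weights, _node_labels(n_nodes), density, seed)
        coupling *= 0.6
    raise StabilityError(
        f"could not stabilise a density-{density} network in {max_attempts} attempts"
    )


def simulate_neural(
    net: GroundTruthNetwork,
    T: int,
    dt: float = 0.01,
    noise_sd: float = 1.0,
    seed: int = 0,
    max_amplitude: float | None = None,
) -> TimeSeriesMatrix:
    """Euler-Maruyama integration of ``dV/dt = W V + noise_sd dW``.

    The first ~10% of the trajectory (``ceil(T/9)`` extra samples prepended)
    is discarded as burn-in; the returned series has exactly ``T`` samples.
    ``max_amplitude`` (default ``10 x`` the largest theoretical stationary
    standard deviation) aborts diverging runs.
    """
    if T < 2:
        raise ValueError("need T >= 2")
    W = net.weights
    n = net.n_nodes
    step = np.eye(n) + dt * W
    if np.max(np.abs(np.linalg.eigvals(step))) >= 1:
        raise StabilityError("Euler step is unstable at this dt; reduce dt")
    if max_amplitude is None and noise_sd > 0:
        from scipy.linalg import solve_continuous_lyapunov

        sigma = solve_continuous_lyapunov(W, -noise_sd ** 2 * np.eye(n))
        max_amplitude = 10.0 * math.sqrt(float(np.max(np.diag(sigma))))

    rng = np.random.default_rng(seed)
    burn = math.ceil(T / 9)
    total = T + burn
    out = np.zeros((n, total))
    v = np.zeros(n)
    sq = math.sqrt(dt) * noise_sd
    for t in range(total):
        out[:, t] = v
        v = step @ v
        if noise_sd > 0:
            v += sq * rng.standard_normal(n)
        if max_amplitude is not None and np.max(np.abs(v)) > max_amplitude:
            raise StabilityError(f"trajectory exceeded amplitude bound {max_amplitude:g}")
    return TimeSeriesMatrix(out[:, burn:], list(net.labels), dt, kind="neural")


def _nonlinear_rates(state: np.ndarray, u: np.ndarray, p: BalloonParams) -> np.ndarray:
    """Time derivatives of the four haemodynamic states (absolute variables)."""
    s, f, v, q = state
    f = np.maximum(f, 1e-9)
    v = np.maximum(v, 1e-9)
    inv_alpha = 1.0 / p.alpha
    extraction = 1.0 - (1.0 - p.rho) ** (1.0 / f)
    ds = p.eta * u - p.kappa * s - p.gamma * (f - 1.0)
    df = s
    dv = (f - v ** inv_alpha) / p.tau
    dq = (f * extraction / p.rho - v ** (inv_alpha - 1.0) * q) / p.tau
    return np.stack([ds, df, dv, dq])


def _linear_system(p: BalloonParams) -> tuple[np.ndarray, np.ndarray]:
    """State matrix and input vector of the linearised haemodynamics."""
    cf = flow_extraction_slope(p.rho)
    A = np.array([
        [-p.kappa, -p.gamma, 0.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 1.0 / p.tau, -1.0 / (p.alpha * p.tau), 0.0],
        [0.0, cf / p.tau, -(1.0 / p.alpha - 1.0) / p.tau, -1.0 / p.tau],
    ])
    b = np.array([p.eta, 0.0, 0.0, 0.0])
    return A, b


def balloon_forward(
    V: TimeSeriesMatrix,
    params: BalloonParams,
    linearize: bool = False,
) -> TimeSeriesMatrix:
    """BOLD response of the Balloon-Windkessel model to neural input.

    The four haemodynamic states (vasodilatory signal, inflow, venous
    volume, deoxyhaemoglobin) start at the resting fixed point and are
    integrated per node with fixed-step RK4 at the input's ``dt``
    (``dt <= 0.01 s`` recommended).  ``linearize=True`` integrates the
    linearisation around rest instead, which is the regime inverted by
    :func:`dcovnet.hemodynamics.backward_reconstruct`.
    """
    if V.kind != "neural":
        raise ValueError(f"expected a neural time series, got kind={V.kind!r}")
    u = V.values
    n, T = u.shape
    h = V.dt
    coeffs = balloon_coefficients(params)
    k1, k2, k3 = coeffs.k
    y = np.zeros((n, T))

    if linearize:
        A, b = _linear_system(params)
        x = np.zeros((4, n))

        def rate(x, ut):
            return A @ x + np.outer(b, ut)

        def readout(x):
            return -params.V0 * ((k1 + k2) * x[3] + (k3 - k2) * x[2])
    else:
        x = np.zeros((4, n))
        x[1:] = 1.0  # f = v = q = 1 at rest

        def rate(x, ut):
            return _nonlinear_rates(x, ut, params)

        def readout(x):
            v, q = x[2], x[3]
            return params.V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))

    y[:, 0] = readout(x)
    for t in range(T - 1):
        u0 = u[:, t]
        u1 = u[:, t + 1]
        um = 0.5 * (u0 + u1)
        r1 = rate(x, u0)
        r2 = rate(x + 0.5 * h * r1, um)
        r3 = rate(x + 0.5 * h * r2, um)
        r4 = rate(x + h * r3, u1)
        x = x + (h / 6.0) * (r1 + 2.0 * r2 + 2.0 * r3 + r4)
        if not np.all(np.isfinite(x)):
            raise StabilityError("haemodynamic state became non-finite")
        y[:, t + 1] = readout(x)
    return TimeSeriesMatrix(y, list(V.labels), V.dt, kind="bold")


def downsample(ts: TimeSeriesMatrix, TR: float) -> TimeSeriesMatrix:
    """Keep every ``TR/dt``-th sample; ``TR`` must be an integer multiple of ``dt``."""
    ratio = TR / ts.dt
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-6 * factor:
        raise ValueError(f"TR={TR} is not an integer multiple of dt={ts.dt}")
    return TimeSeriesMatrix(ts.values[:, ::factor].copy(), list(ts.labels), TR, kind=ts.kind)


def surrogate_sc(net: GroundTruthNetwork, convention: str = "mouse") -> SurrogateSC:
    """Structural-connectivity surrogate of the generating network.

    ``mouse``: off-diagonal |weights| rank-quantised into seven equal-mass
    ordinal bins (1 = weakest .. 7 = strongest), diagonal fixed at 7.
    ``dmri``: symmetrised ``|W| + |W^T|`` with zero diagonal.
    """
    W = net.weights
    n = net.n_nodes
    if convention == "mouse":
        mask = ~np.eye(n, dtype=bool)
        vals = np.abs(W[mask])
        ranks = rankdata(vals, method="min")  # ties share the lowest rank
        bins = 1 + np.floor(7.0 * (ranks - 1) / vals.size).astype(int)
        bins = np.minimum(bins, 7)
        out = np.full((n, n), 7.0)
        out[mask] = bins
        return SurrogateSC(out, list(net.labels), symmetric=False, convention="mouse")
    if convention == "dmri":
        out = np.abs(W) + np.abs(W.T)
        np.fill_diagonal(out, 0.0)
        return SurrogateSC(out, list(net.labels), symmetric=True, convention="dmri")
    raise ValueError("convention must be 'mouse' or 'dmri'")


DEFAULT_CONFOUND_NAMES = [
    "age",
    "weight",
    "height",
    "bp_systolic",
    "bp_diastolic",
    "total_brain_volume",
]


def surrogate_behavior(
    efficiencies: np.ndarray,
    coupling: float,
    confounds: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_noise_measures: int = 8,
    missing_fraction: float = 0.0,
    confound_loadings: np.ndarray | None = None,
    confound_names: list[str] | None = None,
) -> BehaviorTable:
    """Subject behavior table with one planted measure.

    The planted measure (``planted_rt``, a reaction-time-like readout) is
    ``coupling * efficiency + confounds @ loadings + noise``; the remaining
    ``n_noise_measures`` measures are pure unit-variance noise.  Confound
    columns are included in the table as measures in their own right (they
    are behavioral records such as age or weight) and are never masked;
    the planted and noise measures each have entries set missing (NaN)
    independently with probability ``missing_fraction``.
    """
    eff = np.asarray(efficiencies, dtype=float)
    n = eff.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    names = list(confound_names) if confound_names is not None else list(DEFAULT_CONFOUND_NAMES)
    if confounds is None:
        confounds = rng.standard_normal((n, len(names)))
    confounds = np.asarray(confounds, dtype=float)
    if confounds.shape[0] != n:
        raise ValueError("confound rows must match subject count")
    if confounds.shape[1] != len(names):
        raise ValueError("confound columns must match confound names")
    if confound_loadings is None:
        loadings = np.zeros(confounds.shape[1])
    else:
        loadings = np.asarray(confound_loadings, dtype=float)

    planted = coupling * eff + confounds @ loadings + noise_sd * rng.standard_normal(n)
    noise = rng.standard_normal((n, n_noise_measures))

    measures = np.column_stack([planted[:, None], confounds, noise])
    measure_names = (
        ["planted_rt"] + names + [f"noise_{i}" for i in range(n_noise_measures)]
    )
    if missing_fraction > 0:
        maskable = np.ones(len(measure_names), dtype=bool)
        maskable[1 : 1 + len(names)] = False
        miss = rng.random((n, len(measure_names))) < missing_fraction
        measures[miss & maskable[None, :]] = np.nan

    subjects = [f"subj{i:04d}" for i in range(n)]
    return BehaviorTable(subjects, measures, measure_names, names)


def bandlimited_signal(
    n_nodes: int,
    T: int,
    dt: float,
    fmin: float = 0.02,
    fmax: float = 0.2,
    n_components: int = 12,
    amplitude: float = 1.0,
    seed: int = 0,
) -> TimeSeriesMatrix:
    """Smooth band-limited multichannel signal (sum of random sinusoids).

    Emulates slow neural fluctuations in the resting-state band; useful
    wherever high-order numerical derivatives must stay accurate.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(T) * dt
    out = np.zeros((n_nodes, T))
    for i in range(n_nodes):
        freqs = rng.uniform(fmin, fmax, n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, n_components)
        amps = rng.uniform(0.5, 1.0, n_components)
        out[i] = (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None])).sum(0)
        out[i] *= amplitude / max(np.std(out[i]), 1e-12)
    return TimeSeriesMatrix(out, _node_labels(n_nodes), dt, kind="neural")
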