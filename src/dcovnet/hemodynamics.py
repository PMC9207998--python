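"""Backward reconstruction of neural signals from BOLD via the linearised
Balloon model.

The haemodynamic forward model maps neural activity ``V`` through a
vasodilatory signal, blood inflow, venous volume ``v`` and deoxyhaemoglobin
content ``q`` to the BOLD readout

    y = V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)).

Linearised around the resting fixed point the whole chain is a linear
time-invariant system, and applying the fourth-order differential operator

    P(D) = (tau D + 1/alpha) (D + 1/tau) (D^2 + kappa D + gamma)
         = p4 D^4 + p3 D^3 + p2 D^2 + p1 D + p0

to ``y`` collapses it onto a surrogate neural signal

    z = P(D) y = q1 dV/dt + q0 V ,

a fixed linear combination of the true neural signal and its derivative.
:func:`balloon_coefficients` evaluates ``p``, ``q`` and ``k`` from the
biophysical parameters; :func:`backward_reconstruct` applies the operator
with central finite differences.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import savgol_filter

from .containers import BalloonParams, ReconstructionCoefficients, TimeSeriesMatrix

__all__ = [
    "balloon_coefficients",
    "numerical_derivative",
    "backward_reconstruct",
]


def flow_extraction_slope(rho: float) -> float:
    """Linearised slope of ``f * E(f) / rho`` at resting inflow ``f = 1``.

    ``E(f) = 1 - (1 - rho)**(1/f)`` is the oxygen-extraction fraction; the
    slope ``1 + (1 - rho) ln(1 - rho) / rho`` drives the deoxyhaemoglobin
    response to inflow.
    """
    return 1.0 + (1.0 - rho) * math.log(1.0 - rho) / rho


def balloon_coefficients(params: BalloonParams) -> ReconstructionCoefficients:
    """Reconstruction coefficients ``p0..p4``, ``q0..q1`` and ``k1..k3``.

    The ``p`` coefficients are those of the characteristic polynomial of the
    linearised haemodynamic cascade; the ``q`` coefficients follow from the
    same linearisation applied to the BOLD readout, so that
    ``P(D) y = q1 V' + q0 V`` holds identically for the linear forward model.
    """
    tau, alpha, kappa, gamma = params.tau, params.alpha, params.kappa, params.gamma
    k1 = 4.3 * params.theta0 * params.rho * params.TE
    k2 = params.epsilon * params.r0 * params.rho * params.TE
    k3 = 1.0 - params.epsilon

    p4 = tau
    p3 = 1.0 + 1.0 / alpha + tau * kappa
    p2 = 1.0 / (tau * alpha) + tau * gamma + (1.0 + 1.0 / alpha) * kappa
    p1 = (1.0 + 1.0 / alpha) * gamma + kappa / (tau * alpha)
    p0 = gamma / (tau * alpha)

    cf = flow_extraction_slope(params.rho)
    q1 = -params.V0 * params.eta * ((k1 + k2) * cf + (k3 - k2))
    q0 = -(params.V0 * params.eta / tau) * (
        (k1 + k2) * ((cf - 1.0) / alpha + 1.0) + (k3 - k2)
    )
    return ReconstructionCoefficients(
        p=np.array([p0, p1, p2, p3, p4]),
        q=np.array([q0, q1]),
        k=np.array([k1, k2, k3]),
    )


# central finite-difference stencils, exact on polynomials up to degree
# (len(stencil) - 1); offsets are symmetric around the evaluation point
_STENCILS = {
    1: (np.array([-0.5, 0.0, 0.5]), 1),
    2: (np.array([1.0, -2.0, 1.0]), 1),
    3: (np.array([-0.5, 1.0, 0.0, -1.0, 0.5]), 2),
    4: (np.array([1.0, -4.0, 6.0, -4.0, 1.0]), 2),
}


def numerical_derivative(
    ts: TimeSeriesMatrix,
    order: int,
    smooth_window: int | None = None,
    smooth_polyorder: int = 3,
) -> TimeSeriesMatrix:
    """Central-difference derivative of the given order (1..4).

    The output is trimmed symmetrically by ``order`` samples at each end so
    that derivatives of successive orders share a common time support after
    trimming to the highest order.  An optional Savitzky-Golay pre-filter
    (``smooth_window`` odd, default off) can be applied before
    differencing.
    """
    if order not in _STENCILS:
        raise ValueError("derivative order must be in 1..4")
    if ts.n_samples <= 2 * order:
        raise ValueError(
            f"need T > {2 * order} samples for an order-{order} derivative, got {ts.n_samples}"
        )
    x = ts.values
    if smooth_window is not None:
        x = savgol_filter(x, smooth_window, smooth_polyorder, axis=1)
    stencil, reach = _STENCILS[order]
    h = ts.dt
    T = x.shape[1]
    out = np.zeros((x.shape[0], T - 2 * reach))
    for c, off in zip(stencil, range(-reach, reach + 1)):
        if c != 0.0:
            out += c * x[:, reach + off : T - reach + off]
    out /= h ** order
    extra = order - reach
    if extra > 0:
        out = out[:, extra:-extra]
    return TimeSeriesMatrix(out, list(ts.labels), ts.dt, kind="derivative")


def backward_reconstruct(
    y: TimeSeriesMatrix,
    params: BalloonParams,
    smooth_window: int | None = None,
) -> TimeSeriesMatrix:
    """Reconstruct the surrogate neural signal ``z`` from BOLD traces.

    ``z = p4 y'''' + p3 y''' + p2 y'' + p1 y' + p0 y`` with all derivative
    orders aligned on the common trimmed support (4 samples off each end).
    The map is linear in ``y`` by construction.
    """
    if y.kind != "bold":
        raise ValueError(f"expected a BOLD time series, got kind={y.kind!r}")
    if y.n_samples <= 8:
        raise ValueError("need T > 8 samples for the 4th-order derivative")
    coeffs = balloon_coefficients(params)
    p = coeffs.p
    trim = 4
    z = p[0] * y.values[:, trim:-trim]
    for order in (1, 2, 3, 4):
        d = numerical_derivative(y, order, smooth_window=smooth_window).values
        cut = trim - order
        if cut > 0:
            d = d[:, cut:-cut]
        z = z + p[order] * d
    return TimeSeriesMatrix(z, list(y.labels), y.dt, kind="reconstructed")
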