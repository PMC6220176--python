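"""Zero-order ultrasensitive ERK switch coupled to the excitable network.

Active ERK (state ``Z``, a single well-mixed variable) obeys

    dZ/dt = c1·( U_E·(c2 − Z)/(c3 + (c2 − Z)) − c4·Z/(c3 + Z) − c5·Z )

a Goldbeter–Koshland-type push–pull cycle: a drive-dependent activation
term and a saturating deactivation term share the Michaelis constant
``c3``; when ``c3`` is small relative to the convertible pool ``c2`` both
converting reactions run near saturation and the steady-state response to
the drive ``U_E`` becomes switch-like (zero-order ultrasensitivity).  The
linear ``c5·Z`` loss speeds the off-kinetics.  The drive is the spatial
mean of the excitable network's inhibitor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .en_core import ENTrajectory
from .errors import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErkParams:
    """Constants of the ultrasensitive switch (model units)."""

    c1: float = 0.1  # overall rate scale (1/time)
    c2: float = 1.0  # total convertible ERK pool (conc)
    c3: float = 0.05  # shared Michaelis constant (conc); c3 << c2 => zero-order
    c4: float = 0.3  # maximal deactivation drive (conc)
    c5: float = 0.1  # linear decay gain, sharpens the off-transition

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0 or self.c3 <= 0:
            raise InvalidInputError("c1, c2, c3 must be positive")
        if self.c4 < 0 or self.c5 < 0:
            raise InvalidInputError("c4 and c5 must be non-negative")


def get_erk_params() -> ErkParams:
    """Default switch parameters used alongside the network presets."""
    return ErkParams()


@dataclass
class ErkTrace:
    """Time course of active ERK and the drive that produced it."""

    times: np.ndarray
    Z: np.ndarray
    U_E: np.ndarray
    params: ErkParams

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.Z) == len(self.U_E)):
            raise InvalidInputError("ErkTrace arrays must have equal length")

    @property
    def normalized(self) -> np.ndarray:
        """Z / c2, the active fraction of the pool."""
        return self.Z / self.params.c2


def erk_rhs(Z, U_E, params: ErkParams):
    """Right-hand side of the switch ODE at state ``Z`` under drive ``U_E``.

    Accepts scalars or arrays (elementwise).
    """
    if not (np.all(np.isfinite(Z)) and np.all(np.isfinite(U_E))):
        raise InvalidInputError("Z and U_E must be finite")
    c1, c2, c3, c4, c5 = params.c1, params.c2, params.c3, params.c4, params.c5
    return c1 * (U_E * (c2 - Z) / (c3 + (c2 - Z)) - c4 * Z / (c3 + Z) - c5 * Z)


def erk_steady_state(U_E: float, params: ErkParams) -> float:
    """Unique root of the rhs on [0, c2], by bracketed bisection.

    On the bracket the activation term decreases in Z and both loss terms
    increase, so the rhs crosses zero at most once; rhs(0) >= 0 and
    rhs(c2) <= 0 guarantee the bracket for non-negative drive.
    """
    if U_E < 0:
        raise InvalidInputError("drive must be non-negative")
    f0 = erk_rhs(0.0, U_E, params)
    if f0 <= 0.0:
        return 0.0
    f1 = erk_rhs(params.c2, U_E, params)
    if f1 >= 0.0:
        return params.c2
    return float(
        brentq(erk_rhs, 0.0, params.c2, args=(U_E, params), xtol=1e-12, rtol=1e-15)
    )


#: Sentinel when the response never reaches 90% of its asymptote.
ULTRASENSITIVITY_UNDEFINED = float("nan")


def ultrasensitivity_ratio(
    params: ErkParams, n_grid: int = 400, span_decades: tuple[float, float] = (-4, 4)
) -> float:
    """EC90/EC10 of the steady-state dose–response Z*(U_E).

    A Michaelian (hyperbolic) response gives 81; zero-order operation
    (c3 << c2) compresses the ratio far below that.  Returns NaN if the
    response never reaches 90% of its plateau over the scanned range
    (e.g. c4 = 0, where there is no sigmoid to measure).
    """
    if params.c4 <= 0:
        return ULTRASENSITIVITY_UNDEFINED
    drives = np.logspace(span_decades[0], span_decades[1], n_grid) * params.c4
    response = np.array([erk_steady_state(u, params) for u in drives])
    plateau = response[-1]
    if plateau <= 0 or response[0] > 0.1 * plateau or response[-1] < 1e-12:
        return ULTRASENSITIVITY_UNDEFINED
    targets = {}
    for frac in (0.1, 0.9):
        level = frac * plateau
        k = int(np.searchsorted(response, level))
        if k == 0 or k >= n_grid:
            return ULTRASENSITIVITY_UNDEFINED
        # log-linear interpolation between bracketing grid points
        x0, x1 = np.log(drives[k - 1]), np.log(drives[k])
        y0, y1 = response[k - 1], response[k]
        targets[frac] = np.exp(x0 + (level - y0) * (x1 - x0) / (y1 - y0))
    return float(targets[0.9] / targets[0.1])


def simulate_erk(
    U_E_trace: np.ndarray,
    params: ErkParams,
    Z0: float = 0.0,
    dt_erk: float = 1.0,
    t0: float = 0.0,
) -> ErkTrace:
    """Integrate the switch under a uniformly sampled drive.

    Classic RK4 with the drive held piecewise-constant over each step.
    The state is clipped to [0, c2] after each step to absorb the solver's
    O(dt^5) overshoot at the saturated rails.
    """
    U_E_trace = np.asarray(U_E_trace, dtype=float)
    if U_E_trace.ndim != 1 or U_E_trace.size < 2:
        raise InvalidInputError("drive must be a 1-D array of >= 2 samples")
    if np.any(U_E_trace < 0):
        raise InvalidInputError("drive must be non-negative (floor upstream)")
    if not 0.0 <= Z0 <= params.c2:
        raise InvalidInputError(f"Z0 must lie in [0, c2], got {Z0}")
    if dt_erk <= 0:
        raise InvalidInputError("dt_erk must be positive")

    n = U_E_trace.size
    times = t0 + dt_erk * np.arange(n)
    Z = np.empty(n)
    Z[0] = Z0
    z = Z0
    h = dt_erk
    for k in range(n - 1):
        u = U_E_trace[k]
        k1 = erk_rhs(z, u, params)
        k2 = erk_rhs(z + 0.5 * h * k1, u, params)
        k3 = erk_rhs(z + 0.5 * h * k2, u, params)
        k4 = erk_rhs(z + h * k3, u, params)
        z = z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        z = min(max(z, 0.0), params.c2)
        Z[k + 1] = z
    return ErkTrace(times=times, Z=Z, U_E=U_E_trace.copy(), params=params)


def couple_en_to_erk(
    traj: ENTrajectory, params: ErkParams | None = None, Z0: float = 0.0
) -> ErkTrace:
    """Drive the switch with the spatial mean of the network's inhibitor.

    Transient negative undershoots of mean Y are floored at zero (the
    switch presumes a non-negative activation drive); the number of
    floored samples is logged for transparency.
    """
    params = params or get_erk_params()
    if len(traj.times) < 2:
        raise InvalidInputError("trajectory has fewer than 2 samples")
    drive = np.asarray(traj.mean_Y, dtype=float)
    n_neg = int(np.sum(drive < 0))
    if n_neg:
        logger.info("flooring %d negative drive samples at 0", n_neg)
        drive = np.maximum(drive, 0.0)
    return simulate_erk(
        drive,
        params,
        Z0=Z0,
        dt_erk=traj.sample_dt,
        t0=float(traj.times[0]),
    )
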