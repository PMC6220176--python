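"""Stochastic excitable activator–inhibitor network on a periodic cell perimeter.

The protrusion-generating signaling network is modeled as a two-species
reaction–diffusion system on a 1-D ring (the cell boundary).  The
activator ``X`` is autocatalytic and triggers a delayed negative feedback
through the inhibitor ``Y``:

    dX/dt = D_X ∇²X − a1·X − a2·(Y − R)·X + a3·X²/(a4² + X²) + a5 + U_N
    dY/dt = D_Y ∇²Y + ε·(−Y + b1·X)

``R`` is an external (growth-factor-like) stimulus and ``U_N`` a zero-mean
white-noise input acting on the activator only.  The ring is discretized
with central differences (300 points by default) and integrated with a
fixed-step Euler–Maruyama scheme (dt = 0.01 time units).

Time units are model seconds; a single scale factor
(``MODEL_SECONDS_PER_MINUTE``) maps model time to displayed minutes when
simulation output is compared with imaging-cadence data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    InvalidGridError,
    InvalidInputError,
    NoRestStateError,
    NumericalInstabilityError,
)

#: Model seconds displayed as one minute of wall-clock imaging time.  The
#: integrator step (0.01 model s) resolves the fast activator kinetics while
#: pulse trains play out over displayed minutes; this factor is the single,
#: configurable bridge between the two scales.
MODEL_SECONDS_PER_MINUTE = 10.0


@dataclass(frozen=True)
class ExcitableParams:
    """All constants of the activator–inhibitor system plus grid settings.

    Units are model units: concentrations are dimensionless activity
    levels, time is in model seconds, and the ring coordinate is in grid
    units (``dx`` = 1 grid spacing by default; no physical length claim
    is made).
    """

    D_X: float = 1.0  # activator diffusion (length^2/time)
    D_Y: float = 5.0  # inhibitor diffusion; faster, for lateral inhibition
    a1: float = 1.0  # activator linear decay (1/time)
    a2: float = 2.0  # inhibition coupling (1/(conc*time))
    a3: float = 10.0  # autocatalysis maximal rate (conc/time)
    a4: float = 1.0  # autocatalysis half-saturation (conc)
    a5: float = 0.02  # basal production (conc/time)
    epsilon: float = 0.08  # inhibitor time-scale factor (1/time)
    b1: float = 3.0  # inhibitor gain from activator (dimensionless)
    sigma_N: float = 0.0  # white-noise std of U_N (conc/sqrt(time))
    n_points: int = 300
    dt: float = 0.01
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidGridError(f"n_points must be >= 3, got {self.n_points}")
        if self.dt <= 0 or self.dx <= 0:
            raise InvalidInputError("dt and dx must be positive")
        if self.a4 <= 0:
            raise InvalidInputError("a4 (half-saturation) must be positive")
        if self.epsilon <= 0:
            raise InvalidInputError("epsilon must be positive")
        if self.sigma_N < 0:
            raise InvalidInputError("sigma_N must be non-negative")
        cfl = self.dt * max(self.D_X, self.D_Y) / self.dx**2
        if cfl > 0.5:
            raise InvalidInputError(
                f"explicit-scheme stability violated: dt*max(D)/dx^2 = {cfl:.3g} > 0.5"
            )


#: Named parameter regimes.  ``high_threshold`` fires rare, localized
#: excursions (discrete ERK pulses); ``low_threshold`` lowers the inhibitor
#: gain and raises the noise so firings are frequent and ERK stays on.
_PRESETS: dict[str, dict[str, float]] = {
    "high_threshold": {"b1": 3.0, "sigma_N": 0.035},
    "low_threshold": {"b1": 2.2, "sigma_N": 0.16},
}


def get_preset(name: str) -> ExcitableParams:
    """Return one of the named parameter presets.

    ``high_threshold`` and ``low_threshold`` differ only in the inhibitor
    gain ``b1`` and the noise level ``sigma_N``, the two knobs that set
    the firing threshold and the spontaneous firing rate.
    """
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return ExcitableParams(**overrides)


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise external stimulus R(θ, t) applied to the activator equation.

    Each segment is ``(t_start, t_end, profile)`` with ``profile`` a
    per-grid-point amplitude vector; overlapping segments add.
    """

    segments: tuple[tuple[float, float, np.ndarray], ...] = ()

    def __post_init__(self) -> None:
        for t0, t1, profile in self.segments:
            if not t0 < t1:
                raise InvalidInputError(f"segment needs t_start < t_end, got [{t0}, {t1}]")
            profile = np.asarray(profile)
            if not np.all(np.isfinite(profile)) or np.any(profile < 0):
                raise InvalidInputError("stimulus amplitudes must be finite and >= 0")

    def validate_grid(self, n_points: int) -> None:
        for _, _, profile in self.segments:
            if np.asarray(profile).shape != (n_points,):
                raise InvalidInputError(
                    f"stimulus profile length {np.asarray(profile).size} != n_points {n_points}"
                )

    def at(self, t: float, n_points: int) -> np.ndarray:
        """Total stimulus vector at time ``t`` (active on [t_start, t_end))."""
        R = np.zeros(n_points)
        for t0, t1, profile in self.segments:
            if t0 <= t < t1:
                R += profile
        return R

    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls()

    @classmethod
    def uniform(
        cls, amplitude: float, t_start: float, t_end: float, n_points: int
    ) -> "StimulusProtocol":
        """Spatially uniform stimulus (EGF-like bath application)."""
        return cls(((t_start, t_end, np.full(n_points, float(amplitude))),))

    @classmethod
    def patch(
        cls,
        amplitude: float,
        t_start: float,
        t_end: float,
        n_points: int,
        center: int,
        width: int,
    ) -> "StimulusProtocol":
        """Localized stimulus on a contiguous arc of ``width`` grid points."""
        profile = np.zeros(n_points)
        idx = (np.arange(width) + center - width // 2) % n_points
        profile[idx] = float(amplitude)
        return cls(((t_start, t_end, profile),))


@dataclass
class ENState:
    """Instantaneous state of the network on the ring."""

    X: np.ndarray
    Y: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape != self.Y.shape or self.X.ndim != 1:
            raise InvalidInputError("X and Y must be 1-D arrays of equal length")


@dataclass
class ENTrajectory:
    """Sampled space–time fields of a simulation run.

    ``mean_Y`` — the spatial mean of the inhibitor at each sample — is the
    aggregate output that drives the downstream ERK switch (U_E).
    """

    times: np.ndarray
    X_kymo: np.ndarray  # (n_samples, n_points)
    Y_kymo: np.ndarray
    mean_Y: np.ndarray
    seed: int | None
    params: ExcitableParams

    def __post_init__(self) -> None:
        n = len(self.times)
        if self.X_kymo.shape != self.Y_kymo.shape or self.X_kymo.shape[0] != n:
            raise InvalidInputError("trajectory array shapes inconsistent")
        if len(self.mean_Y) != n:
            raise InvalidInputError("mean_Y length does not match times")

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def times_minutes(
        self, model_seconds_per_minute: float = MODEL_SECONDS_PER_MINUTE
    ) -> np.ndarray:
        """Sample times on the displayed-minutes scale."""
        return self.times / model_seconds_per_minute


def periodic_laplacian(field: np.ndarray, dx: float) -> np.ndarray:
    """Central-difference Laplacian on a periodic 1-D grid.

    ``out[i] = (field[i-1] - 2 field[i] + field[i+1]) / dx^2`` with index
    wraparound.  The discrete operator is conservative: the output sums to
    zero for any field.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 1 or field.size < 3:
        raise InvalidGridError("periodic Laplacian needs a 1-D field of >= 3 points")
    if dx <= 0:
        raise InvalidInputError("dx must be positive")
    return (np.roll(field, 1) - 2.0 * field + np.roll(field, -1)) / dx**2


def en_drift(
    state: ENState, params: ExcitableParams, R_now: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic drift (dX/dt, dY/dt) of the activator–inhibitor system."""
    X, Y = state.X, state.Y
    R_now = np.asarray(R_now, dtype=float)
    if X.shape != (params.n_points,) or R_now.shape != X.shape:
        raise InvalidInputError(
            f"shape mismatch: X {X.shape}, R {R_now.shape}, n_points {params.n_points}"
        )
    dX = (
        params.D_X * periodic_laplacian(X, params.dx)
        - params.a1 * X
        - params.a2 * (Y - R_now) * X
        + params.a3 * X**2 / (params.a4**2 + X**2)
        + params.a5
    )
    dY = params.D_Y * periodic_laplacian(Y, params.dx) + params.epsilon * (
        -Y + params.b1 * X
    )
    return dX, dY


def em_step(
    state: ENState,
    params: ExcitableParams,
    R_now: np.ndarray,
    rng: np.random.Generator,
) -> ENState:
    """One Euler–Maruyama step.

    The white-noise input acts on the activator only, with the standard
    sqrt(dt) scaling; the inhibitor update is deterministic.  Identical
    generator states give identical output.
    """
    dX, dY = en_drift(state, params, R_now)
    dt = params.dt
    X_new = state.X + dt * dX
    if params.sigma_N > 0:
        X_new = X_new + np.sqrt(dt) * params.sigma_N * rng.standard_normal(
            params.n_points
        )
    Y_new = state.Y + dt * dY
    if not (np.all(np.isfinite(X_new)) and np.all(np.isfinite(Y_new))):
        raise NumericalInstabilityError(
            f"non-finite state after Euler–Maruyama step at t = {state.t + dt:.4g}"
        )
    return ENState(X=X_new, Y=Y_new, t=state.t + dt)


def _uniform_drift_x(X: float, params: ExcitableParams) -> float:
    """Scalar activator drift of the spatially uniform system on Y = b1*X."""
    Y = params.b1 * X
    return (
        -params.a1 * X
        - params.a2 * Y * X
        + params.a3 * X**2 / (params.a4**2 + X**2)
        + params.a5
    )


def find_rest_state(params: ExcitableParams) -> tuple[float, float]:
    """Stable uniform fixed point (X*, Y*) of the deterministic system.

    On the uniform manifold dY = 0 forces Y = b1*X, reducing the problem
    to a scalar root find for the activator drift.  The smallest root is
    the rest state; a negative drift slope there certifies stability.
    """
    if params.a5 == 0.0:
        return 0.0, 0.0  # origin solves the drift exactly
    # Bracket the smallest root on a dense grid; rest lies near a5/a1.
    x_hi = max(10.0 * params.a4, 10.0 * params.a5 / params.a1, 1.0)
    xs = np.linspace(0.0, x_hi, 20001)
    fs = np.array([_uniform_drift_x(x, params) for x in xs])
    sign_change = np.nonzero((fs[:-1] > 0) & (fs[1:] <= 0))[0]
    if sign_change.size == 0:
        raise NoRestStateError(
            "no down-crossing of the uniform activator drift found; "
            "system has no stable uniform rest state in the scanned range"
        )
    i = sign_change[0]
    X_rest = brentq(_uniform_drift_x, xs[i], xs[i + 1], args=(params,), xtol=1e-14)
    return float(X_rest), float(params.b1 * X_rest)


def rest_state_vectors(params: ExcitableParams) -> tuple[np.ndarray, np.ndarray]:
    """Rest state broadcast onto the grid, for initializing simulations."""
    X_rest, Y_rest = find_rest_state(params)
    return np.full(params.n_points, X_rest), np.full(params.n_points, Y_rest)


def simulate_en(
    params: ExcitableParams,
    protocol: StimulusProtocol | None = None,
    duration: float = 600.0,
    sample_every: int = 100,
    seed: int | None = None,
    initial_state: ENState | None = None,
) -> ENTrajectory:
    """Integrate the network for ``duration`` model seconds.

    The trajectory is sampled every ``sample_every`` integrator steps
    (default: every model second at dt = 0.01).  The run starts from the
    deterministic rest state unless ``initial_state`` is given, and is
    bitwise reproducible for a fixed ``seed``.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be positive")
    if sample_every < 1:
        raise InvalidInputError("sample_every must be >= 1")
    protocol = protocol or StimulusProtocol.none()
    protocol.validate_grid(params.n_points)

    if initial_state is None:
        X, Y = rest_state_vectors(params)
        state = ENState(X=X, Y=Y, t=0.0)
    else:
        state = ENState(
            X=initial_state.X.copy(), Y=initial_state.Y.copy(), t=initial_state.t
        )
    rng = np.random.default_rng(seed)

    n_steps = int(round(duration / params.dt))
    n_samples = n_steps // sample_every + 1
    times = np.empty(n_samples)
    X_kymo = np.empty((n_samples, params.n_points))
    Y_kymo = np.empty((n_samples, params.n_points))

    # Precompute the stimulus only at segment boundaries: R is piecewise
    # constant in time, so rebuild the vector when a boundary is crossed.
    boundaries = sorted(
        {t for t0, t1, _ in protocol.segments for t in (t0, t1)}
    )
    R_now = protocol.at(state.t, params.n_points)
    next_boundary_idx = 0
    while (
        next_boundary_idx < len(boundaries)
        and boundaries[next_boundary_idx] <= state.t
    ):
        next_boundary_idx += 1

    sample_idx = 0
    times[0] = state.t
    X_kymo[0] = state.X
    Y_kymo[0] = state.Y
    sample_idx = 1

    for step in range(1, n_steps + 1):
        if (
            next_boundary_idx < len(boundaries)
            and state.t >= boundaries[next_boundary_idx] - 0.5 * params.dt
        ):
            R_now = protocol.at(boundaries[next_boundary_idx], params.n_points)
            next_boundary_idx += 1
        state = em_step(state, params, R_now, rng)
        if step % sample_every == 0:
            times[sample_idx] = state.t
            X_kymo[sample_idx] = state.X
            Y_kymo[sample_idx] = state.Y
            sample_idx += 1

    times = times[:sample_idx]
    X_kymo = X_kymo[:sample_idx]
    Y_kymo = Y_kymo[:sample_idx]
    return ENTrajectory(
        times=times,
        X_kymo=X_kymo,
        Y_kymo=Y_kymo,
        mean_Y=Y_kymo.mean(axis=1),
        seed=seed,
        params=params,
    )


def _deterministic(params: ExcitableParams) -> ExcitableParams:
    return replace(params, sigma_N=0.0)


def _perturbed_run(
    params: ExcitableParams,
    amplitude: float,
    patch_width: int,
    duration: float,
) -> ENTrajectory:
    """Deterministic run with an instantaneous activator kick on a patch."""
    X, Y = rest_state_vectors(params)
    idx = (np.arange(patch_width) + params.n_points // 2 - patch_width // 2) % (
        params.n_points
    )
    X = X.copy()
    X[idx] += amplitude
    return simulate_en(
        _deterministic(params),
        duration=duration,
        sample_every=10,
        seed=0,
        initial_state=ENState(X=X, Y=Y, t=0.0),
    )


@dataclass
class ThresholdProbeResult:
    """Response curve of peak mean-activator excursion vs kick amplitude."""

    amplitudes: np.ndarray
    peak_excursions: np.ndarray
    threshold: float | None  # midpoint of the bracketing amplitudes, None if no jump
    excitable: bool

    def __bool__(self) -> bool:  # truthiness = "a firing threshold exists"
        return self.excitable


def threshold_probe(
    params: ExcitableParams,
    amplitudes: Sequence[float],
    patch_width: int = 20,
    duration: float = 100.0,
) -> ThresholdProbeResult:
    """Probe all-or-none behaviour with deterministic patch perturbations.

    Each amplitude is added instantaneously to the activator on a
    contiguous arc at rest and the peak excursion of the spatial mean of X
    is recorded.  An excitable system shows a sharp jump: suprathreshold
    responses cluster (within ~25% of each other) and dwarf subthreshold
    ones.  A missing jump yields ``excitable=False`` rather than an error.
    """
    amplitudes = np.asarray(sorted(amplitudes), dtype=float)
    X_rest, _ = find_rest_state(params)
    peaks = np.empty(amplitudes.size)
    for k, amp in enumerate(amplitudes):
        if amp == 0:
            peaks[k] = 0.0
            continue
        traj = _perturbed_run(params, amp, patch_width, duration)
        peaks[k] = float(np.max(traj.X_kymo.mean(axis=1)) - X_rest)
    # Locate the largest multiplicative jump between consecutive responses;
    # near-zero responses are floored at 1e-3 of the curve maximum so that
    # the jump is measured against a meaningful subthreshold scale.
    threshold = None
    excitable = False
    floor = 1e-3 * peaks.max() + 1e-300
    ratios = peaks[1:] / np.maximum(peaks[:-1], floor)
    if peaks.size >= 2:
        j = int(np.argmax(ratios))
        above = peaks[j + 1 :]
        below_max = peaks[: j + 1].max(initial=0.0)
        if (
            above.size > 0
            and above.min() >= 5.0 * max(below_max, 1e-12)
            and (above.size < 2 or above.max() <= 1.25 * above.min())
        ):
            threshold = float(0.5 * (amplitudes[j] + amplitudes[j + 1]))
            excitable = True
    return ThresholdProbeResult(
        amplitudes=amplitudes,
        peak_excursions=peaks,
        threshold=threshold,
        excitable=excitable,
    )


#: Sentinel returned when every tested gap is still refractory.
GREATER_THAN_MAX_GAP = float("inf")


def refractory_period(
    params: ExcitableParams,
    probe_amplitude: float,
    gaps: Sequence[float],
    patch_width: int = 20,
    recovery_fraction: float = 0.8,
    response_window: float = 60.0,
) -> float:
    """Smallest tested gap at which a second firing recovers to 80% of the first.

    Two identical suprathreshold kicks are applied ``gap`` apart to the
    deterministic system; the run returns the smallest gap whose
    second-response peak reaches ``recovery_fraction`` of the first.
    Returns ``GREATER_THAN_MAX_GAP`` (inf) if every gap is refractory.
    """
    gaps = sorted(float(g) for g in gaps)
    first_peak = None
    for gap in gaps:
        ratio, first_peak = _paired_pulse_ratio(
            params, probe_amplitude, gap, patch_width, response_window
        )
        if first_peak <= 0:
            raise InvalidInputError("probe amplitude produced no first response")
        if ratio >= recovery_fraction:
            return gap
    return GREATER_THAN_MAX_GAP


def _paired_pulse_ratio(
    params: ExcitableParams,
    probe_amplitude: float,
    gap: float,
    patch_width: int,
    response_window: float,
) -> tuple[float, float]:
    """(second/first peak ratio, first peak) for one paired-pulse gap.

    The second response is isolated by subtracting a single-kick control
    run from the double-kick run, so that an overlap of the two responses
    cannot masquerade as recovery.
    """
    det = _deterministic(params)
    X_rest, _ = find_rest_state(params)
    idx = (np.arange(patch_width) + params.n_points // 2 - patch_width // 2) % (
        params.n_points
    )
    duration = gap + response_window
    control = _perturbed_run(params, probe_amplitude, patch_width, duration)
    mean_control = control.X_kymo.mean(axis=1)
    first_peak = float(np.max(mean_control) - X_rest)

    k = int(np.searchsorted(control.times, gap))
    X2 = control.X_kymo[k].copy()
    Y2 = control.Y_kymo[k].copy()
    X2[idx] += probe_amplitude
    double = simulate_en(
        det,
        duration=response_window,
        sample_every=10,
        seed=0,
        initial_state=ENState(X=X2, Y=Y2, t=float(control.times[k])),
    )
    mean_double = double.X_kymo.mean(axis=1)
    n = min(len(mean_double), len(mean_control) - k)
    second_peak = float(np.max(mean_double[1:n] - mean_control[k + 1 : k + n]))
    return second_peak / first_peak, first_peak


def second_response_ratio(
    params: ExcitableParams,
    probe_amplitude: float,
    gap: float,
    patch_width: int = 20,
    response_window: float = 60.0,
) -> float:
    """Peak ratio (second kick / first kick) for one paired-pulse gap."""
    ratio, _ = _paired_pulse_ratio(
        params, probe_amplitude, gap, patch_width, response_window
    )
    return ratio
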