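"""Canonical simulation experiments on the coupled network–switch model.

These drivers reproduce the model's characteristic behaviours:

* spontaneous regimes — rare localized firings driving discrete ERK
  pulses (high threshold) vs frequent firings driving sustained ERK
  activation (low threshold);
* stimulus protocols — a sustained uniform stimulus produces a global
  first firing followed by repeated, refractory-period-paced ERK peaks,
  while a transient stimulus produces a single peak of comparable
  magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .en_core import (
    ENTrajectory,
    ExcitableParams,
    StimulusProtocol,
    get_preset,
    refractory_period,
    simulate_en,
    threshold_probe,
)
from .erk_switch import ErkParams, ErkTrace, couple_en_to_erk

#: Noise level used in stimulus-protocol experiments.  The protocol runs
#: characterize the deterministic stimulus response; a small residual
#: noise keeps the setting realistic without seeding spontaneous firings
#: that would confound the stimulus-evoked peaks.
PROTOCOL_SIGMA = 0.01

#: Uniform stimulus amplitude for the growth-factor protocols.  Chosen to
#: be comfortably suprathreshold while leaving the driven oscillation slow
#: enough for the ERK switch to track each cycle.
STIMULUS_AMPLITUDE = 0.3


def regime_run(
    preset: str | ExcitableParams,
    duration: float = 1200.0,
    seed: int = 0,
    erk_params: ErkParams | None = None,
    sample_every: int = 100,
) -> tuple[ENTrajectory, ErkTrace]:
    """Spontaneous (unstimulated) run of a preset, coupled to the switch."""
    params = get_preset(preset) if isinstance(preset, str) else preset
    traj = simulate_en(params, duration=duration, sample_every=sample_every, seed=seed)
    erk = couple_en_to_erk(traj, erk_params)
    return traj, erk


def stimulus_run(
    kind: str,
    preset: str | ExcitableParams = "high_threshold",
    amplitude: float = STIMULUS_AMPLITUDE,
    onset: float = 100.0,
    short_duration: float = 30.0,
    duration: float = 1000.0,
    seed: int = 0,
    sigma_N: float = PROTOCOL_SIGMA,
    erk_params: ErkParams | None = None,
) -> tuple[ENTrajectory, ErkTrace]:
    """Uniform-stimulus run: ``kind`` is ``"long"`` (sustained) or ``"short"``.

    A long stimulus stays on from ``onset`` to the end of the run; a short
    one switches off after ``short_duration`` model seconds.
    """
    params = get_preset(preset) if isinstance(preset, str) else preset
    params = replace(params, sigma_N=sigma_N)
    if kind == "long":
        t_off = duration
    elif kind == "short":
        t_off = onset + short_duration
    else:
        raise ValueError(f"kind must be 'long' or 'short', got {kind!r}")
    protocol = StimulusProtocol.uniform(amplitude, onset, t_off, params.n_points)
    traj = simulate_en(
        params, protocol=protocol, duration=duration, sample_every=100, seed=seed
    )
    erk = couple_en_to_erk(traj, erk_params)
    return traj, erk


def count_discrete_pulses(
    z_norm: np.ndarray, high: float = 0.5, low: float = 0.1
) -> int:
    """Number of discrete ERK pulses in a normalized activity trace.

    A pulse is counted when the trace crosses ``high``×max having
    previously returned below ``low``×max — i.e. pulses separated by
    near-complete switch-off, the signature of the discrete regime.
    """
    z_norm = np.asarray(z_norm, dtype=float)
    zmax = z_norm.max()
    if zmax <= 0:
        return 0
    n = 0
    armed = True
    for z in z_norm:
        if armed and z > high * zmax:
            n += 1
            armed = False
        elif z < low * zmax:
            armed = True
    return n


def fraction_time_above(z_norm: np.ndarray, level: float = 0.5) -> float:
    """Fraction of samples above ``level``×max (sustained-activation metric)."""
    z_norm = np.asarray(z_norm, dtype=float)
    zmax = z_norm.max()
    if zmax <= 0:
        return 0.0
    return float(np.mean(z_norm > level * zmax))


def first_excursion_coverage(
    traj: ENTrajectory,
    after_time: float = 0.0,
    activity_level: float = 1.0,
    window: float = 40.0,
) -> float:
    """Peak fraction of perimeter active during the first firing after ``after_time``.

    A grid point is active when its activator exceeds ``activity_level``
    (well above rest, well below the excursion plateau).  Returns 0 if no
    firing occurs.
    """
    sel = traj.times >= after_time
    active_frac = (traj.X_kymo[sel] > activity_level).mean(axis=1)
    times = traj.times[sel]
    fired = np.nonzero(active_frac > 0)[0]
    if fired.size == 0:
        return 0.0
    k0 = fired[0]
    in_window = times <= times[k0] + window
    return float(active_frac[k0 : np.sum(in_window)].max())


def erk_peaks(
    erk: ErkTrace, min_height_frac: float = 0.3, min_prominence_frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """(peak times, normalized peak heights) of an ERK trace."""
    zn = erk.normalized
    zmax = zn.max()
    if zmax <= 0:
        return np.array([]), np.array([])
    idx, _ = find_peaks(
        zn,
        height=min_height_frac * zmax,
        prominence=min_prominence_frac * zmax,
        distance=10,
    )
    return erk.times[idx], zn[idx]


@dataclass
class ExcitabilityReport:
    """Threshold and refractory characterization of a parameter set."""

    threshold: float
    refractory: float
    probe_amplitude: float


def characterize_excitability(
    params: ExcitableParams,
    patch_width: int = 20,
    gaps: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0, 55.0, 60.0, 70.0, 85.0, 100.0),
) -> ExcitabilityReport:
    """Measure the firing threshold and the refractory period.

    The threshold comes from a deterministic amplitude scan; the
    refractory period is then probed with a just-suprathreshold kick
    (1.5× threshold), the classic protocol — a strong probe would force
    firing during the relative refractory phase and understate it.
    """
    amps = [0.0125 * 2**k for k in range(8)]  # 0.0125 .. 1.6
    probe = threshold_probe(params, amps, patch_width=patch_width)
    if not probe.excitable or probe.threshold is None:
        raise ValueError("parameter set is not excitable over the scanned range")
    probe_amp = 1.5 * probe.threshold
    refractory = refractory_period(
        params, probe_amplitude=probe_amp, gaps=gaps, patch_width=patch_width
    )
    return ExcitabilityReport(
        threshold=probe.threshold, refractory=refractory, probe_amplitude=probe_amp
    )
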