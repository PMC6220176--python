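"""Ground-truthed synthetic inputs for every analysis stage.

Two levels of fixture are generated, both bitwise-reproducible under a
fixed seed:

* paired activity traces (:func:`synth_traces`) — protrusion activity as
  a sum of Gaussian bumps, and a reporter trace that echoes each bump
  with a planted delay and coupling gain;
* rendered movies (:func:`synth_movie`, :func:`render_from_model`) — a
  roughly circular adherent cell with a nucleus, boundary protrusions as
  ramped intensity bumps on a marker channel, delayed
  nucleus-to-cytoplasm reporter redistribution whose magnitude scales
  with protrusion size, optional interior flashes, optional additive read
  noise.

The reporter redistribution conserves total reporter intensity per frame
(nuclear loss = cytoplasmic gain), so C/N changes are translocation-
driven, and a volume channel carries the same multiplicative shape
artifact as the reporter so that volume normalization is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError
from .fdm_imaging import ImageStack, point_at
from .trace_metrics import Trace


@dataclass(frozen=True)
class ProtrusionSpec:
    """One planted boundary protrusion."""

    angle: float  # radians on the perimeter (package angle convention)
    onset: float  # minutes
    duration: float  # minutes
    bump_size: float = 6.0  # bump disc radius, pixels
    amplitude_fold: float = 2.5  # local intensity multiple at full ramp

    @property
    def magnitude(self) -> float:
        """Planted protrusion magnitude: the fold change above baseline."""
        return self.amplitude_fold - 1.0


@dataclass(frozen=True)
class FlashSpec:
    """One planted interior activity flash (no boundary change)."""

    angle: float
    onset: float
    duration: float
    patch_radius: float = 5.0
    amplitude_pct: float = 25.0  # percent intensity increase
    radial_fraction: float = 0.45  # patch center radius / cell radius


@dataclass
class SynthConfig:
    """Configuration of the rendered synthetic movie."""

    image_size: tuple[int, int] = (96, 96)
    frame_interval: float = 1.0  # minutes
    duration: float = 360.0  # minutes (6 h of imaging)
    cell_radius: float = 30.0
    nucleus_radius: float = 10.0
    protrusion_schedule: list[ProtrusionSpec] = field(default_factory=list)
    interior_flash_schedule: list[FlashSpec] = field(default_factory=list)
    erk_delay: float = 5.0  # minutes from protrusion onset to C/N rise
    erk_gain: float = 0.25  # fractional C/N increase per unit magnitude
    ramp_minutes: float = 2.0  # protrusion intensity ramp-up time
    cn_pulse_rise: float = 3.0  # minutes to C/N pulse peak
    cn_pulse_fall: float = 4.0
    noise_sigma: float = 0.0  # additive Gaussian read noise, intensity units
    baseline_intensity: float = 100.0
    volume_artifact_amp: float = 0.0  # cytoplasm shape-artifact modulation
    volume_artifact_period: float = 47.0  # minutes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise InvalidConfigError("nucleus_radius must be < cell_radius")
        if self.frame_interval <= 0 or self.duration <= 0:
            raise InvalidConfigError("frame_interval and duration must be positive")
        for ev in list(self.protrusion_schedule) + list(self.interior_flash_schedule):
            if not (0 <= ev.onset and ev.onset + ev.duration <= self.duration):
                raise InvalidConfigError(
                    f"scheduled event [{ev.onset}, {ev.onset + ev.duration}] "
                    f"outside [0, {self.duration}]"
                )
        for p in self.protrusion_schedule:
            if p.amplitude_fold <= 1:
                raise InvalidConfigError("amplitude_fold must exceed 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))

    @property
    def center(self) -> tuple[float, float]:
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)


def default_config(seed: int = 0, noise_sigma: float = 0.0) -> SynthConfig:
    """Standard study movie: 4 boundary protrusions and 2 interior flashes
    over 6 h at 1 frame/min."""
    protrusions = [
        ProtrusionSpec(angle=0.5, onset=50.0, duration=10.0, amplitude_fold=2.8),
        ProtrusionSpec(angle=2.1, onset=130.0, duration=9.0, amplitude_fold=3.0),
        ProtrusionSpec(angle=3.6, onset=210.0, duration=11.0, amplitude_fold=2.6),
        ProtrusionSpec(angle=5.2, onset=290.0, duration=9.0, amplitude_fold=3.2),
    ]
    flashes = [
        FlashSpec(angle=1.2, onset=95.0, duration=4.0),
        FlashSpec(angle=4.3, onset=255.0, duration=4.0),
    ]
    return SynthConfig(
        protrusion_schedule=protrusions,
        interior_flash_schedule=flashes,
        noise_sigma=noise_sigma,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Everything the generators know about what they planted."""

    protrusion_events: list[ProtrusionSpec]
    flash_events: list[FlashSpec]
    true_cn_trace: Trace | None
    true_lag: float
    cell_mask: np.ndarray | None = None  # H x W (static geometry)
    nucleus_mask: np.ndarray | None = None
    pulse_onsets: np.ndarray | None = None  # minutes, trace-level fixtures
    pulse_amplitudes: np.ndarray | None = None


def synth_traces(
    true_lag: float = 5.0,
    n_pulses: int = 8,
    pulse_width: float = 4.0,
    coupling_gain: float = 1.0,
    noise_sigma: float = 0.0,
    duration: float = 360.0,
    frame_interval: float = 1.0,
    seed: int = 0,
    baseline: float = 1.0,
) -> tuple[Trace, Trace, GroundTruth]:
    """Paired protrusion/reporter traces with a planted lag and coupling.

    The protrusion trace is a sum of Gaussian bumps (width
    ``pulse_width`` min, s.d. = width/2.355) at seeded random onsets kept
    at least 2.5 bump widths apart; the reporter trace is baseline 1.0
    plus each bump delayed by ``true_lag`` and scaled by
    ``coupling_gain`` (times a seeded per-pulse amplitude factor), plus
    white noise on both.
    """
    if n_pulses * pulse_width >= duration:
        raise InvalidConfigError("schedule overcrowded: n_pulses*pulse_width >= duration")
    rng = np.random.default_rng(seed)
    t = frame_interval * np.arange(int(round(duration / frame_interval)))
    margin = 3.0 * pulse_width + true_lag
    min_gap = 2.5 * pulse_width
    onsets: list[float] = []
    for _ in range(20000):
        if len(onsets) == n_pulses:
            break
        cand = rng.uniform(margin, duration - margin)
        if all(abs(cand - o) >= min_gap for o in onsets):
            onsets.append(cand)
    if len(onsets) < n_pulses:
        raise InvalidConfigError("could not place pulses without >50% overlap")
    onsets = np.sort(np.asarray(onsets))
    amplitudes = rng.uniform(0.6, 1.4, size=n_pulses)

    sd = pulse_width / 2.355  # FWHM -> s.d.
    prot = np.full_like(t, baseline)  # integrated-intensity traces sit on a baseline
    erk = np.full_like(t, baseline)
    for o, a in zip(onsets, amplitudes):
        prot += a * np.exp(-0.5 * ((t - o) / sd) ** 2)
        erk += coupling_gain * a * np.exp(-0.5 * ((t - o - true_lag) / sd) ** 2)
    if noise_sigma > 0:
        prot = prot + noise_sigma * rng.standard_normal(t.size)
        erk = erk + noise_sigma * rng.standard_normal(t.size)
    gt = GroundTruth(
        protrusion_events=[],
        flash_events=[],
        true_cn_trace=None,
        true_lag=true_lag,
        pulse_onsets=onsets,
        pulse_amplitudes=amplitudes,
    )
    return (
        Trace(times=t, values=prot, label="protrusion"),
        Trace(times=t, values=erk, label="reporter"),
        gt,
    )


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ramp(t: np.ndarray, onset: float, duration: float, ramp: float) -> np.ndarray:
    """0→1 linear ramp over ``ramp`` minutes, hold, then off after the event."""
    up = np.clip((t - onset) / max(ramp, 1e-9), 0.0, 1.0)
    return np.where(t < onset + duration, up, 0.0)


def _triangle(t: np.ndarray, start: float, rise: float, fall: float) -> np.ndarray:
    up = (t - start) / rise
    down = 1.0 - (t - start - rise) / fall
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def true_cn_fraction(config: SynthConfig, times: np.ndarray) -> np.ndarray:
    """Planted fractional C/N increase over baseline at each frame time."""
    f = np.zeros_like(times)
    for p in config.protrusion_schedule:
        f += (
            config.erk_gain
            * p.magnitude
            * _triangle(
                times,
                p.onset + config.erk_delay,
                config.cn_pulse_rise,
                config.cn_pulse_fall,
            )
        )
    return f


def synth_movie(config: SynthConfig) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Render the four-channel study movie and its ground truth.

    Channels: ``protrusion`` (membrane biosensor with planted bumps and
    interior flashes), ``reporter`` (translocation reporter), ``volume``
    (uniform volume marker) and ``membrane`` (constant membrane marker).
    """
    H, W = config.image_size
    T = config.n_frames
    t = config.frame_interval * np.arange(T)
    center = config.center
    cell = _disc((H, W), center, config.cell_radius)
    nucleus = _disc((H, W), center, config.nucleus_radius)
    cyto = cell & ~nucleus
    base = config.baseline_intensity

    # --- protrusion-marker channel ---------------------------------------
    prot_chan = np.empty((T, H, W))
    prot_chan[:] = np.where(cell, base, 0.0)
    bump_masks = []
    for p in config.protrusion_schedule:
        bc = point_at(np.array(center), config.cell_radius, p.angle)
        bump = _disc((H, W), bc, p.bump_size) & cell
        if not bump.any():
            raise InvalidConfigError("protrusion bump lies outside the frame/cell")
        bump_masks.append(bump)
        gain = p.magnitude * _ramp(t, p.onset, p.duration, config.ramp_minutes)
        prot_chan[:, bump] += base * gain[:, None]
    for fl in config.interior_flash_schedule:
        fc = point_at(
            np.array(center), config.cell_radius * fl.radial_fraction, fl.angle
        )
        patch = _disc((H, W), fc, fl.patch_radius) & cell
        if not patch.any():
            raise InvalidConfigError("interior flash lies outside the cell")
        on = ((t >= fl.onset) & (t < fl.onset + fl.duration)).astype(float)
        prot_chan[:, patch] += base * (fl.amplitude_pct / 100.0) * on[:, None]

    # --- reporter channel (conserved nucleocytoplasmic redistribution) ---
    n_nuc = int(nucleus.sum())
    n_cyto = int(cyto.sum())
    nuc0, cyto0 = 2.0 * base, 1.0 * base  # rest: nuclear-enriched reporter
    total = nuc0 * n_nuc + cyto0 * n_cyto
    r0 = cyto0 / nuc0
    frac = true_cn_fraction(config, t)
    ratio = r0 * (1.0 + frac)
    nuc_val = total / (ratio * n_cyto + n_nuc)  # per-pixel nuclear intensity
    cyto_val = ratio * nuc_val
    reporter = np.zeros((T, H, W))
    reporter[:, nucleus] = nuc_val[:, None]
    reporter[:, cyto] = cyto_val[:, None]

    # --- volume channel with shared shape artifact ------------------------
    volume = np.zeros((T, H, W))
    volume[:, cell] = base
    if config.volume_artifact_amp > 0:
        art = 1.0 + config.volume_artifact_amp * np.sin(
            2 * np.pi * t / config.volume_artifact_period
        )
        reporter[:, cyto] *= art[:, None]
        volume[:, cyto] *= art[:, None]

    membrane = np.zeros((T, H, W))
    membrane[:, cell] = base

    channels = {
        "protrusion": prot_chan,
        "reporter": reporter,
        "volume": volume,
        "membrane": membrane,
    }
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        for name in channels:
            noisy = channels[name] + config.noise_sigma * rng.standard_normal(
                channels[name].shape
            )
            channels[name] = np.clip(noisy, 0.0, None)

    stacks = {
        name: ImageStack(
            data=data, frame_interval=config.frame_interval, channel=name
        )
        for name, data in channels.items()
    }
    gt = GroundTruth(
        protrusion_events=list(config.protrusion_schedule),
        flash_events=list(config.interior_flash_schedule),
        true_cn_trace=Trace(times=t, values=r0 * (1.0 + frac), label="true C/N"),
        true_lag=config.erk_delay,
        cell_mask=cell,
        nucleus_mask=nucleus,
    )
    return stacks, gt


def render_from_model(
    traj,
    erk,
    config: SynthConfig | None = None,
    model_seconds_per_minute: float | None = None,
    activity_to_fold: float = 0.5,
    cn_gain: float = 0.5,
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Render a movie driven by a simulated network trajectory and ERK trace.

    The activator field X(θ, t) modulates marker intensity in the
    boundary band at matching perimeter angles (fold = 1 +
    ``activity_to_fold``·X); the ERK state Z(t) drives a global conserved
    reporter redistribution with fractional C/N increase =
    ``cn_gain``·Z/c2.  Both are resampled to the movie frame interval.
    """
    from .en_core import MODEL_SECONDS_PER_MINUTE

    config = config or SynthConfig(seed=0)
    spm = model_seconds_per_minute or MODEL_SECONDS_PER_MINUTE
    H, W = config.image_size
    center = config.center
    cell = _disc((H, W), center, config.cell_radius)
    nucleus = _disc((H, W), center, config.nucleus_radius)
    cyto = cell & ~nucleus
    base = config.baseline_intensity

    sim_minutes = traj.times / spm
    frame_times = np.arange(0.0, sim_minutes[-1], config.frame_interval)
    if len(frame_times) < 2:
        raise InvalidConfigError("trajectory too short for the frame interval")
    T = len(frame_times)
    n_grid = traj.X_kymo.shape[1]
    X_frames = np.empty((T, n_grid))
    for g in range(n_grid):
        X_frames[:, g] = np.interp(frame_times, sim_minutes, traj.X_kymo[:, g])
    erk_minutes = erk.times / spm
    Z_frames = np.interp(frame_times, erk_minutes, erk.normalized)

    # assign every cell-boundary-band pixel to its perimeter angle bin
    rr, cc = np.nonzero(cell)
    radius = np.hypot(rr - center[0], cc - center[1])
    band_sel = radius >= config.cell_radius - 3.0
    angles = (np.arctan2(center[0] - rr, cc - center[1]) % (2 * np.pi))[band_sel]
    bins = np.minimum((angles / (2 * np.pi) * n_grid).astype(int), n_grid - 1)
    band_rows, band_cols = rr[band_sel], cc[band_sel]

    prot_chan = np.empty((T, H, W))
    prot_chan[:] = np.where(cell, base, 0.0)
    folds = 1.0 + activity_to_fold * np.clip(X_frames, 0.0, None)
    prot_chan[:, band_rows, band_cols] *= folds[:, bins]

    frac = cn_gain * Z_frames
    n_nuc, n_cyto = int(nucleus.sum()), int(cyto.sum())
    nuc0, cyto0 = 2.0 * base, 1.0 * base
    total = nuc0 * n_nuc + cyto0 * n_cyto
    r0 = cyto0 / nuc0
    ratio = r0 * (1.0 + frac)
    nuc_val = total / (ratio * n_cyto + n_nuc)
    reporter = np.zeros((T, H, W))
    reporter[:, nucleus] = nuc_val[:, None]
    reporter[:, cyto] = (ratio * nuc_val)[:, None]

    volume = np.zeros((T, H, W))
    volume[:, cell] = base
    membrane = volume.copy()

    channels = {
        "protrusion": prot_chan,
        "reporter": reporter,
        "volume": volume,
        "membrane": membrane,
    }
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        for name in channels:
            channels[name] = np.clip(
                channels[name]
                + config.noise_sigma * rng.standard_normal(channels[name].shape),
                0.0,
                None,
            )
    stacks = {
        name: ImageStack(data=d, frame_interval=config.frame_interval, channel=name)
        for name, d in channels.items()
    }
    gt = GroundTruth(
        protrusion_events=[],
        flash_events=[],
        true_cn_trace=Trace(times=frame_times, values=ratio, label="true C/N"),
        true_lag=float("nan"),
        cell_mask=cell,
        nucleus_mask=nucleus,
    )
    return stacks, gt
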