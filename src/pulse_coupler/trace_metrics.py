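"""Quantification of reporter traces and protrusion–ERK temporal coupling.

Covers the single-cell readouts used throughout the pipeline:

* C/N ratio — cytoplasmic over nuclear mean intensity of a kinase
  translocation reporter (rises when the kinase is active), optionally
  normalized to a volume marker to cancel shape artifacts;
* FRET ratio — acceptor/donor (YFP/CFP) mean intensity over the cell;
* membrane normalization — pixelwise biosensor over membrane marker;
* pulse calling — events with a fractional rise above a configurable
  threshold (default 20%) over the preceding local-minimum baseline;
* lag analysis — lagged Pearson cross-correlation and per-event-pair
  half-maximum rise-time differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, InvalidMaskError
from .fdm_imaging import CellMask, ImageStack


@dataclass
class Trace:
    """A uniformly sampled scalar time series (minutes)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidInputError("times and values must be 1-D and equal length")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise InvalidInputError("times must be strictly increasing")
            if np.ptp(dt) > 1e-9 * max(1.0, abs(dt[0])):
                raise InvalidInputError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class PulseEvent:
    """A pulse called on a trace: baseline, peak and fractional rise."""

    onset_time: float  # time of the baseline local minimum
    peak_time: float
    baseline: float
    peak: float
    fractional_increase: float
    fused: bool = False
    onset_index: int = -1
    peak_index: int = -1


@dataclass
class Correlogram:
    """Lagged Pearson correlation between two traces."""

    lags: np.ndarray  # minutes, symmetric about 0
    coefficients: np.ndarray  # Pearson r per lag; NaN where undefined
    best_lag: float  # minutes; positive = second trace follows the first

    @property
    def best_r(self) -> float:
        k = int(np.nanargmax(self.coefficients))
        return float(self.coefficients[k])


def _masked_mean(frame: np.ndarray, mask: np.ndarray, what: str, i: int) -> float:
    if not mask.any():
        raise InvalidMaskError(f"empty {what} mask at frame {i}")
    return float(frame[mask].mean())


def cn_ratio(
    reporter: ImageStack,
    nuc_mask: np.ndarray,
    cyto_mask: np.ndarray,
    volume: ImageStack | None = None,
) -> Trace:
    """Cytoplasmic-to-nuclear ratio of a translocation reporter.

    ``nuc_mask``/``cyto_mask`` are per-frame boolean arrays (T × H × W or
    a single H × W applied to every frame).  With a ``volume`` channel the
    reporter ratio is divided by the volume-channel ratio, cancelling
    shape-driven apparent redistribution.
    """
    nuc_mask = _broadcast_mask(nuc_mask, reporter)
    cyto_mask = _broadcast_mask(cyto_mask, reporter)
    if np.any(nuc_mask & cyto_mask):
        raise InvalidMaskError("nuclear and cytoplasmic masks overlap")
    values = np.empty(reporter.n_frames)
    for i in range(reporter.n_frames):
        c = _masked_mean(reporter.data[i], cyto_mask[i], "cytoplasmic", i)
        n = _masked_mean(reporter.data[i], nuc_mask[i], "nuclear", i)
        r = c / n
        if volume is not None:
            cv = _masked_mean(volume.data[i], cyto_mask[i], "cytoplasmic", i)
            nv = _masked_mean(volume.data[i], nuc_mask[i], "nuclear", i)
            r /= cv / nv
        values[i] = r
    times = reporter.frame_interval * np.arange(reporter.n_frames)
    return Trace(times=times, values=values, label="C/N")


def _broadcast_mask(mask: np.ndarray, stack: ImageStack) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 2:
        mask = np.broadcast_to(mask, stack.shape)
    if mask.shape != stack.shape:
        raise InvalidMaskError(
            f"mask shape {mask.shape} does not match stack {stack.shape}"
        )
    return mask


def fret_ratio(yfp: ImageStack, cfp: ImageStack, mask: CellMask) -> Trace:
    """Mean YFP over mean CFP inside the cell mask, per frame (FRET proxy)."""
    if yfp.shape != cfp.shape:
        raise InvalidInputError("YFP and CFP stacks must be aligned frame-for-frame")
    values = np.empty(yfp.n_frames)
    for i in range(yfp.n_frames):
        m = mask.masks[min(i, mask.n_frames - 1)]
        cfp_mean = _masked_mean(cfp.data[i], m, "cell", i)
        if cfp_mean == 0:
            raise InvalidInputError(f"zero CFP mean at frame {i}")
        values[i] = _masked_mean(yfp.data[i], m, "cell", i) / cfp_mean
    times = yfp.frame_interval * np.arange(yfp.n_frames)
    return Trace(times=times, values=values, label="YFP/CFP")


def membrane_normalize(
    biosensor: ImageStack, membrane_marker: ImageStack, floor: float
) -> np.ndarray:
    """Pixelwise biosensor / membrane-marker ratio.

    Pixels where the marker falls below ``floor`` are NaN (masked), never
    infinite.
    """
    if biosensor.shape != membrane_marker.shape:
        raise InvalidInputError("biosensor and marker stacks must be aligned")
    marker = membrane_marker.data
    with np.errstate(divide="ignore", invalid="ignore"):
        out = biosensor.data / marker
    out[marker < floor] = np.nan
    return out


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(values, size=window, mode="nearest")


def _local_extrema(v: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local minima and maxima; plateau ties resolve to the
    earlier sample (strictly greater than the left, at least the right)."""
    minima, maxima = [], []
    n = len(v)
    for i in range(n):
        left = v[i - 1] if i > 0 else np.inf
        right = v[i + 1] if i < n - 1 else -np.inf
        if v[i] > left and v[i] >= right:
            maxima.append(i)
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < n - 1 else np.inf
        if v[i] < left and v[i] <= right:
            minima.append(i)
    if not minima or (maxima and maxima[0] < minima[0]):
        minima.insert(0, 0)  # leading baseline for a rise from the start
    return minima, maxima


def detect_pulses(
    trace: Trace,
    min_fractional_increase: float = 0.20,
    smoothing_window: int = 3,
) -> list[PulseEvent]:
    """Call pulses whose fractional rise over baseline exceeds the threshold.

    After optional moving-average smoothing, each local maximum is
    compared with its preceding local minimum (the baseline); an event is
    emitted when (peak − baseline)/baseline > ``min_fractional_increase``.
    Qualifying maxima that share a baseline (overlapping rises) are fused
    into a single flagged event whose peak is the highest (earliest on
    ties).  Deterministic.
    """
    if len(trace.times) < 5:
        raise InvalidInputError("trace too short for pulse detection (need >= 5)")
    v = _smooth(trace.values, smoothing_window)
    minima, maxima = _local_extrema(v)
    events: list[PulseEvent] = []
    by_baseline: dict[int, list[int]] = {}
    for pk in maxima:
        prior = [m for m in minima if m < pk]
        if not prior:
            continue
        base_idx = prior[-1]
        baseline = v[base_idx]
        if baseline <= 0:
            continue
        frac = (v[pk] - baseline) / baseline
        if frac > min_fractional_increase:
            by_baseline.setdefault(base_idx, []).append(pk)
    for base_idx, peaks in sorted(by_baseline.items()):
        best = max(peaks, key=lambda k: (v[k], -k))
        baseline = v[base_idx]
        events.append(
            PulseEvent(
                onset_time=float(trace.times[base_idx]),
                peak_time=float(trace.times[best]),
                baseline=float(baseline),
                peak=float(v[best]),
                fractional_increase=float((v[best] - baseline) / baseline),
                fused=len(peaks) > 1,
                onset_index=base_idx,
                peak_index=best,
            )
        )
    return events


def cross_correlation(a: Trace, b: Trace, max_lag: float) -> Correlogram:
    """Pearson correlation of ``a`` and ``b`` at integer-frame lags.

    For lag L, ``b`` is shifted so that r(L) = corr(a(t), b(t + L)); a
    positive ``best_lag`` therefore means ``b`` follows ``a``.  Ties in r
    break toward the smallest |lag|, then toward the negative lag.
    Zero-variance overlaps give NaN at that lag and are excluded from the
    argmax.
    """
    if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
        raise InvalidInputError("traces must share an identical sampling grid")
    dt = a.dt
    span = a.times[-1] - a.times[0]
    if max_lag >= span / 2:
        raise InvalidInputError("max_lag must be less than half the trace duration")
    kmax = int(np.floor(max_lag / dt))
    lags_k = np.arange(-kmax, kmax + 1)
    coeffs = np.empty(lags_k.size)
    for idx, k in enumerate(lags_k):
        if k >= 0:
            x, y = a.values[: len(a.values) - k or None], b.values[k:]
        else:
            x, y = a.values[-k:], b.values[:k]
        if x.std() == 0 or y.std() == 0:
            coeffs[idx] = np.nan
            continue
        coeffs[idx] = float(np.corrcoef(x, y)[0, 1])
    finite = np.isfinite(coeffs)
    if not finite.any():
        raise InsufficientDataError("correlation undefined at every lag")
    rmax = np.nanmax(coeffs)
    candidates = np.nonzero(finite & (coeffs >= rmax - 1e-12))[0]
    best_idx = min(candidates, key=lambda i: (abs(int(lags_k[i])), int(lags_k[i])))
    return Correlogram(
        lags=lags_k * dt, coefficients=coeffs, best_lag=float(lags_k[best_idx] * dt)
    )


def half_rise_time(trace: Trace, event: PulseEvent) -> float:
    """First crossing of baseline + 0.5·(peak − baseline) on the rising edge.

    Linearly interpolated between samples of the raw trace values.
    """
    level = event.baseline + 0.5 * (event.peak - event.baseline)
    v = trace.values
    for i in range(max(event.onset_index, 0), event.peak_index):
        if v[i] <= level <= v[i + 1] and v[i + 1] > v[i]:
            f = (level - v[i]) / (v[i + 1] - v[i])
            return float(trace.times[i] + f * (trace.times[i + 1] - trace.times[i]))
    return float(trace.times[event.peak_index])


@dataclass
class LagResult:
    """Per-pair half-maximum lags and their summary statistics."""

    lags: np.ndarray  # minutes, one per paired event
    mean: float
    sem: float
    n_pairs: int
    unmatched: int  # ERK pulses with no preceding protrusion peak in window


def half_max_lag(
    protrusion: Trace,
    erk: Trace,
    pairing_window: float = 15.0,
    min_fractional_increase: float = 0.20,
    smoothing_window: int = 3,
) -> LagResult:
    """Half-maximal rise-time lag between paired protrusion and ERK pulses.

    Each ERK pulse is paired with the nearest protrusion peak that
    precedes it (or coincides) within ``pairing_window`` minutes; the lag
    is t_half(ERK) − t_half(protrusion).  Unpaired ERK pulses are counted
    but excluded.
    """
    p_events = detect_pulses(protrusion, min_fractional_increase, smoothing_window)
    e_events = detect_pulses(erk, min_fractional_increase, smoothing_window)
    lags = []
    unmatched = 0
    for ev in e_events:
        prior = [
            p
            for p in p_events
            if 0 <= ev.peak_time - p.peak_time <= pairing_window
        ]
        if not prior:
            unmatched += 1
            continue
        mate = max(prior, key=lambda p: p.peak_time)
        lags.append(half_rise_time(erk, ev) - half_rise_time(protrusion, mate))
    lags = np.asarray(lags)
    if lags.size == 0:
        return LagResult(lags=lags, mean=np.nan, sem=np.nan, n_pairs=0, unmatched=unmatched)
    sem = float(lags.std(ddof=1) / np.sqrt(lags.size)) if lags.size > 1 else 0.0
    return LagResult(
        lags=lags,
        mean=float(lags.mean()),
        sem=sem,
        n_pairs=int(lags.size),
        unmatched=unmatched,
    )


def pulse_magnitude_correlation(
    erk_events: list[PulseEvent], protrusion_magnitudes: np.ndarray
) -> float:
    """Pearson r between ERK pulse fractional increases and paired
    protrusion magnitudes."""
    mags = np.asarray(protrusion_magnitudes, dtype=float)
    if len(erk_events) != mags.size:
        raise InvalidInputError("event list and magnitude list differ in length")
    if mags.size < 3:
        raise InsufficientDataError("need at least 3 event pairs")
    fracs = np.array([e.fractional_increase for e in erk_events])
    return float(stats.pearsonr(fracs, mags)[0])
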