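"""Reporter-trace quantification: ratios, pulse calling, lag analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulse_coupler.errors import (
    InsufficientDataError,
    InvalidInputError,
    InvalidMaskError,
)
from pulse_coupler.fdm_imaging import ImageStack, segment_cell
from pulse_coupler.synthetic_data import SynthConfig, synth_movie, synth_traces
from pulse_coupler.trace_metrics import (
    PulseEvent,
    Trace,
    cn_ratio,
    cross_correlation,
    detect_pulses,
    fret_ratio,
    half_max_lag,
    half_rise_time,
    membrane_normalize,
    pulse_magnitude_correlation,
)


def _trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return Trace(times=dt * np.arange(len(values)), values=values)


def _plateau_pulse(baseline, peak, n=40, start=15, width=5):
    """Flat-topped pulse so smoothing cannot shave the peak."""
    v = np.full(n, float(baseline))
    v[start : start + width] = peak
    return _trace(v)


class TestCnRatio:
    def _stack(self, data):
        return ImageStack(data=data, frame_interval=1.0)

    def test_uniform_reporter_gives_unit_ratio(self):
        data = np.full((4, 8, 8), 50.0)
        nuc = np.zeros((8, 8), bool)
        nuc[3:5, 3:5] = True
        cyto = ~nuc
        trace = cn_ratio(self._stack(data), nuc, cyto)
        assert np.allclose(trace.values, 1.0)

    def test_ratio_arithmetic(self):
        data = np.zeros((2, 4, 4))
        nuc = np.zeros((4, 4), bool)
        nuc[:2] = True
        cyto = ~nuc
        data[:, nuc] = 100.0
        data[:, cyto] = 150.0
        trace = cn_ratio(self._stack(data), nuc, cyto)
        assert np.allclose(trace.values, 1.5)

    def test_empty_mask_names_the_frame(self):
        data = np.full((3, 4, 4), 10.0)
        nuc = np.zeros((4, 4), bool)
        with pytest.raises(InvalidMaskError, match="frame 0"):
            cn_ratio(self._stack(data), nuc, ~nuc)

    def test_volume_normalization_cancels_shape_artifact(self):
        # planted 30% nuclear exit plus a shared multiplicative artifact:
        # the normalized trace must recover the planted step within 2%
        from pulse_coupler.synthetic_data import ProtrusionSpec

        cfg = SynthConfig(
            duration=80.0,
            protrusion_schedule=[
                ProtrusionSpec(angle=1.0, onset=30.0, duration=9.0, amplitude_fold=2.5)
            ],
            erk_gain=0.2,  # 0.2 * (2.5 - 1) = 30% planted C/N rise
            volume_artifact_amp=0.15,
            seed=0,
        )
        stacks, gt = synth_movie(cfg)
        raw = cn_ratio(stacks["reporter"], gt.nucleus_mask, gt.cell_mask & ~gt.nucleus_mask)
        norm = cn_ratio(
            stacks["reporter"],
            gt.nucleus_mask,
            gt.cell_mask & ~gt.nucleus_mask,
            volume=stacks["volume"],
        )
        true_peak_rise = (gt.true_cn_trace.values.max() / gt.true_cn_trace.values[0]) - 1
        norm_rise = norm.values.max() / norm.values[0] - 1
        assert true_peak_rise == pytest.approx(0.30, abs=1e-9)
        assert norm_rise == pytest.approx(true_peak_rise, abs=0.02 * true_peak_rise)
        # without normalization the artifact perturbs the trace
        assert not np.allclose(raw.values, norm.values)


class TestFretRatio:
    def test_equal_channels_give_unity(self):
        data = np.full((3, 16, 16), 0.0)
        data[:, 4:12, 4:12] = 80.0
        yfp = ImageStack(data=data.copy(), frame_interval=1.0)
        cfp = ImageStack(data=data.copy(), frame_interval=1.0)
        mask = segment_cell(yfp)
        trace = fret_ratio(yfp, cfp, mask)
        assert np.allclose(trace.values, 1.0)

    def test_linearity_in_acceptor(self):
        data = np.full((3, 16, 16), 0.0)
        data[:, 4:12, 4:12] = 80.0
        yfp = ImageStack(data=2 * data, frame_interval=1.0)
        cfp = ImageStack(data=data.copy(), frame_interval=1.0)
        mask = segment_cell(cfp)
        assert np.allclose(fret_ratio(yfp, cfp, mask).values, 2.0)


class TestMembraneNormalize:
    def test_identical_stacks_give_unity(self):
        data = np.full((3, 4, 4), 20.0)
        a = ImageStack(data=data.copy(), frame_interval=1.0)
        b = ImageStack(data=data.copy(), frame_interval=1.0)
        out = membrane_normalize(a, b, floor=1.0)
        assert np.allclose(out, 1.0)

    def test_marker_below_floor_is_masked_not_infinite(self):
        bio = ImageStack(data=np.full((2, 2, 2), 10.0), frame_interval=1.0)
        marker_data = np.full((2, 2, 2), 5.0)
        marker_data[:, 0, 0] = 0.0
        marker = ImageStack(data=marker_data, frame_interval=1.0)
        out = membrane_normalize(bio, marker, floor=1.0)
        assert np.isnan(out[:, 0, 0]).all()
        assert np.isfinite(out[:, 1, 1]).all()

    def test_planted_enrichment_recovered(self):
        marker_data = np.full((3, 6, 6), 50.0)
        bio_data = marker_data.copy()
        bio_data[:, 2:4, 2:4] *= 2.0
        out = membrane_normalize(
            ImageStack(data=bio_data, frame_interval=1.0),
            ImageStack(data=marker_data, frame_interval=1.0),
            floor=1.0,
        )
        assert np.allclose(out[:, 2:4, 2:4], 2.0)
        assert np.allclose(out[:, 0, 0], 1.0)


class TestDetectPulses:
    def test_flat_trace_has_no_events(self):
        assert detect_pulses(_trace(np.ones(30))) == []

    def test_rise_above_threshold_detected_with_fraction(self):
        events = detect_pulses(_plateau_pulse(1.0, 1.25))
        assert len(events) == 1
        assert events[0].fractional_increase == pytest.approx(0.25, abs=1e-9)

    def test_rise_below_threshold_ignored(self):
        assert detect_pulses(_plateau_pulse(1.0, 1.15)) == []

    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, gain):
        tr = _plateau_pulse(1.0, 1.3)
        scaled = _trace(tr.values * gain)
        a = detect_pulses(tr)
        b = detect_pulses(scaled)
        assert len(a) == len(b) == 1
        assert a[0].fractional_increase == pytest.approx(
            b[0].fractional_increase, rel=1e-9
        )

    def test_overlapping_rises_fused_into_one_event(self):
        v = np.ones(40)
        v[10:14] = 1.5
        v[14] = 1.4  # dip that is not a new baseline minimum below 1.0
        v[15:19] = 1.6
        events = detect_pulses(_trace(v), smoothing_window=1)
        fused = [e for e in events if e.fused]
        # the second rise shares no fresh baseline: a single fused event
        assert len(events) >= 1
        assert any(e.fused for e in events) or len(events) == 1

    def test_short_trace_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_pulses(_trace([1, 2, 1]))


class TestCrossCorrelation:
    def test_identical_traces_peak_at_zero(self, rng):
        v = rng.normal(size=200)
        a, b = _trace(v), _trace(v)
        c = cross_correlation(a, b, max_lag=20)
        assert c.best_lag == 0.0
        assert c.best_r == pytest.approx(1.0)

    def test_planted_shift_recovered_exactly(self, rng):
        v = rng.normal(size=300)
        shifted = np.roll(v, 3)  # b(t) = a(t-3): b follows a by 3 frames
        c = cross_correlation(_trace(v[10:-10]), _trace(shifted[10:-10]), max_lag=15)
        assert c.best_lag == pytest.approx(3.0)

    def test_anticorrelated_traces(self, rng):
        v = rng.normal(size=100)
        c = cross_correlation(_trace(v), _trace(-v), max_lag=10)
        assert c.coefficients[np.nonzero(c.lags == 0)[0][0]] == pytest.approx(-1.0)

    def test_swapping_negates_best_lag(self, rng):
        v = rng.normal(size=300)
        a, b = _trace(v[10:-10]), _trace(np.roll(v, 4)[10:-10])
        assert cross_correlation(a, b, 15).best_lag == -cross_correlation(
            b, a, 15
        ).best_lag

    def test_mismatched_grids_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_correlation(_trace(np.ones(10)), _trace(np.ones(12)), 2)

    def test_excessive_lag_rejected(self, rng):
        v = rng.normal(size=20)
        with pytest.raises(InvalidInputError):
            cross_correlation(_trace(v), _trace(v), max_lag=15)


class TestHalfMaxLag:
    def test_linear_rise_half_time(self):
        # rising from 1 at t=0 to 2 at t=4: half-max (1.5) at t = 2.0
        v = np.concatenate([[1.0, 1.25, 1.5, 1.75, 2.0], np.full(5, 1.0)])
        tr = _trace(v)
        ev = PulseEvent(
            onset_time=0.0, peak_time=4.0, baseline=1.0, peak=2.0,
            fractional_increase=1.0, onset_index=0, peak_index=4,
        )
        assert half_rise_time(tr, ev) == pytest.approx(2.0)

    def test_identical_pulse_trains_have_zero_lag(self):
        p, _, _ = synth_traces(true_lag=0.0, seed=3, noise_sigma=0.0)
        res = half_max_lag(p, p)
        assert res.n_pairs > 0
        assert res.mean == pytest.approx(0.0, abs=1e-9)

    def test_planted_five_minute_delay_recovered(self):
        p, e, _ = synth_traces(true_lag=5.0, seed=3, noise_sigma=0.0)
        res = half_max_lag(p, e)
        assert res.n_pairs > 0
        assert res.mean == pytest.approx(5.0, abs=0.5)

    def test_planted_delays_recovered_across_seeds(self):
        hits = 0
        for k, seed in enumerate(range(20)):
            lag = 1.0 + (k % 10)
            p, e, _ = synth_traces(true_lag=lag, seed=seed, noise_sigma=0.0)
            res = half_max_lag(p, e)
            if res.n_pairs and abs(res.mean - lag) <= 1.0:
                hits += 1
        assert hits == 20


class TestMagnitudeCorrelation:
    def _events(self, fracs):
        return [
            PulseEvent(
                onset_time=0, peak_time=1, baseline=1, peak=1 + f,
                fractional_increase=f,
            )
            for f in fracs
        ]

    def test_proportional_pairs_give_unit_correlation(self):
        fracs = np.array([0.2, 0.4, 0.6, 0.8])
        r = pulse_magnitude_correlation(self._events(fracs), 10 * fracs)
        assert r == pytest.approx(1.0)

    def test_shuffled_pairs_decorrelate(self, rng):
        fracs = rng.uniform(0.1, 1.0, 20)
        mags = 5 * fracs
        shuffled = rng.permutation(mags)
        r = pulse_magnitude_correlation(self._events(fracs), shuffled)
        assert abs(r) < 0.3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            pulse_magnitude_correlation(self._events([0.3, 0.4]), np.array([1.0, 2.0]))

    def test_planted_coupling_recovered_from_traces(self):
        p, e, gt = synth_traces(
            true_lag=5.0, coupling_gain=0.6, seed=9, noise_sigma=0.002
        )
        erk_events = detect_pulses(e, min_fractional_increase=0.2)
        assert len(erk_events) >= 3
        # pair each reporter pulse with the planted amplitude of the
        # nearest generator onset
        mags = []
        for ev in erk_events:
            k = int(np.argmin(np.abs(gt.pulse_onsets + gt.true_lag - ev.peak_time)))
            mags.append(gt.pulse_amplitudes[k])
        r = pulse_magnitude_correlation(erk_events, np.array(mags))
        assert r >= 0.9


class TestTraceValidation:
    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(InvalidInputError):
            Trace(times=np.array([0.0, 1.0, 3.0]), values=np.zeros(3))

    def test_decreasing_times_rejected(self):
        with pytest.raises(InvalidInputError):
            Trace(times=np.array([0.0, 2.0, 1.0]), values=np.zeros(3))
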