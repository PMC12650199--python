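import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sg

from hcsleep.config import DeltaParams, RippleParams, SpindleParams
from hcsleep.core import ChannelTrace, EventKind, Hypnogram, Modality, Region, Stage
from hcsleep.detection import (
    _bandpass_sos,
    _threshold_runs,
    bandpass_zero_phase,
    detect_delta,
    detect_ripples,
    detect_spindles,
    event_rates,
    normalized_envelope,
    restrict_to_sleep,
)
from hcsleep.errors import DegenerateInputError, ValidationError
from hcsleep.synthetic import delta_template, ripple_template, spindle_template

from oracles import scan_halfwave_events, scan_threshold_events


def _trace(samples, fs=1000.0, region=Region.CA1):
    return ChannelTrace("t", Modality.LFP, region, fs, samples)


class TestBandpass:
    def test_passband_sinusoid_amplitude_preserved(self):
        fs, f0 = 1000.0, 150.0
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = bandpass_zero_phase(_trace(x), (100.0, 250.0)).samples
        mid = slice(1000, 3000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_sinusoid_suppressed(self):
        fs = 1000.0
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_zero_phase(_trace(x), (100.0, 250.0)).samples
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(y[1000:3000]) < 0.05 * rms(x[1000:3000])

    def test_zero_phase_time_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4000)
        fwd = bandpass_zero_phase(_trace(x), (100.0, 250.0)).samples
        rev = bandpass_zero_phase(_trace(x[::-1].copy()), (100.0, 250.0)).samples
        # forward-backward filtering is zero-phase away from edge transients
        interior = slice(500, -500)
        assert np.allclose(fwd[interior], rev[::-1][interior], atol=1e-6)

    def test_symmetric_burst_peak_not_shifted(self):
        fs = 1000.0
        x = np.zeros(4000)
        tpl = ripple_template(0.08, fs)
        x[2000 - tpl.size // 2 : 2000 - tpl.size // 2 + tpl.size] = tpl
        y = bandpass_zero_phase(_trace(x), (100.0, 250.0)).samples
        env_x = np.abs(sg.hilbert(x))
        env_y = np.abs(sg.hilbert(y))
        assert abs(int(np.argmax(env_y)) - int(np.argmax(env_x))) <= 1

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass_zero_phase(_trace(np.zeros(100), fs=200.0), (100.0, 250.0))


class TestNormalizedEnvelope:
    def test_zscore_moments(self, quiet_lfp):
        z = normalized_envelope(quiet_lfp, (100.0, 250.0), "lowpass", 20.0)
        assert abs(z.mean()) < 1e-9
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance(self, quiet_lfp):
        z1 = normalized_envelope(quiet_lfp, (9.0, 17.0), "gaussian", 0.1)
        scaled = _trace(quiet_lfp.samples * 10.0)
        z2 = normalized_envelope(scaled, (9.0, 17.0), "gaussian", 0.1)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalized_envelope(_trace(np.zeros(5000)), (100.0, 250.0))


def _inject(bg, tpl, center_idx, amp):
    x = bg.copy()
    i0 = center_idx - tpl.size // 2
    x[i0 : i0 + tpl.size] += amp * tpl
    return x


def _ripple_amp_for_z(bg, fs, dur, target_z):
    """Amplitude giving roughly target_z on the ripple envelope of bg."""
    from hcsleep.synthetic import _envelope_for_kind, _template_gain

    env = _envelope_for_kind(EventKind.RIPPLE, bg, fs)
    gain = _template_gain(EventKind.RIPPLE, dur, fs)
    # peak envelope excess over the local baseline must reach target_z SDs
    return float(np.sqrt(target_z * env.std() / gain))


class TestRippleDetector:
    fs = 1000.0

    @pytest.fixture(scope="class")
    @staticmethod
    def bg():
        rng = np.random.default_rng(5)
        return rng.standard_normal(60000) * 8.0

    def test_injected_burst_detected_once(self, bg):
        amp = _ripple_amp_for_z(bg, self.fs, 0.08, 8.0)
        x = _inject(bg, ripple_template(0.08, self.fs), 30000, amp)
        events = detect_ripples(_trace(x))
        near = events.df[np.abs(events.df["peak_s"] - 30.0) <= 0.015]
        assert len(near) == 1

    def test_short_burst_rejected_by_duration_floor(self, bg):
        """A 20 ms burst at 6 SD is below the 30 ms minimum duration."""
        amp = _ripple_amp_for_z(bg, self.fs, 0.02, 6.0)
        tpl = ripple_template(0.02, self.fs)
        # iterate against the event/background cross term so the measured
        # envelope peak really sits at 6 SD
        for _ in range(4):
            x = _inject(bg, tpl, 30000, amp)
            z = normalized_envelope(_trace(x), (100.0, 250.0), "lowpass", 20.0)
            achieved = z[29950:30050].max()
            if abs(achieved - 6.0) < 0.2:
                break
            amp *= float(np.sqrt(6.0 / max(achieved, 1.0)))
        events = detect_ripples(_trace(x))
        assert not len(events.df[np.abs(events.df["peak_s"] - 30.0) <= 0.05])

    def test_long_envelope_rejected_by_duration_cap(self, bg):
        """A sustained 150 ms high-envelope segment exceeds the 100 ms cap."""
        t = np.arange(int(0.15 * self.fs)) / self.fs
        tpl = np.sin(2 * np.pi * 150.0 * t)  # flat envelope, 150 ms
        amp = _ripple_amp_for_z(bg, self.fs, 0.15, 10.0)
        x = _inject(bg, tpl, 30000, amp * 2)
        events = detect_ripples(_trace(x))
        assert not len(events.df[np.abs(events.df["peak_s"] - 30.0) <= 0.1])

    def test_low_rate_rejected(self):
        with pytest.raises(ValidationError):
            detect_ripples(_trace(np.zeros(1000), fs=400.0))

    def test_scale_invariance(self, bg):
        amp = _ripple_amp_for_z(bg, self.fs, 0.08, 8.0)
        x = _inject(bg, ripple_template(0.08, self.fs), 30000, amp)
        a = detect_ripples(_trace(x))
        b = detect_ripples(_trace(x * 7.5))
        assert a.df[["start_s", "peak_s", "end_s"]].equals(
            b.df[["start_s", "peak_s", "end_s"]]
        )

    def test_threshold_monotonicity(self, bg):
        counts = []
        for thr in (2.5, 3.0, 4.0, 5.0):
            p = RippleParams(peak_threshold_sd=thr, boundary_threshold_sd=thr)
            counts.append(len(detect_ripples(_trace(bg), p)))
        assert counts == sorted(counts, reverse=True)


class TestDeltaDetector:
    fs = 1000.0

    @pytest.fixture(scope="class")
    @staticmethod
    def bg():
        rng = np.random.default_rng(6)
        # pink-ish slow background
        x = rng.standard_normal(120000)
        sos = sg.butter(2, 20.0, btype="lowpass", fs=1000.0, output="sos")
        return sg.sosfiltfilt(sos, x) * 10.0

    def _amp_for_z(self, bg, dur, target):
        sos = _bandpass_sos((0.1, 5.0), self.fs, 2)
        sd = sg.sosfiltfilt(sos, bg).std()
        tpl = delta_template(dur, self.fs)
        pad = np.zeros(20000)
        iso = np.concatenate([pad, tpl, pad])
        gain = np.abs(sg.sosfiltfilt(sos, iso)).max()
        return target * sd / gain

    def test_injected_halfwave_detected_at_extremum(self, bg):
        amp = self._amp_for_z(bg, 0.3, 3.5)
        x = _inject(bg, delta_template(0.3, self.fs), 60000, amp)
        events = detect_delta(_trace(x, region=Region.MPFC))
        near = events.df[np.abs(events.df["peak_s"] - 60.0) <= 0.02]
        assert len(near) == 1

    def test_overlong_halfwave_rejected(self, bg):
        """A plain 700 ms half-sine exceeds the 500 ms duration cap."""
        tpl = np.sin(np.pi * np.arange(700) / 699)
        sos = _bandpass_sos((0.1, 5.0), self.fs, 2)
        sd = sg.sosfiltfilt(sos, bg).std()
        iso = np.concatenate([np.zeros(20000), tpl, np.zeros(20000)])
        gain = np.abs(sg.sosfiltfilt(sos, iso)).max()
        x = _inject(bg, tpl, 60000, 6.0 * sd / gain)
        events = detect_delta(_trace(x, region=Region.MPFC))
        assert not len(events.df[np.abs(events.df["peak_s"] - 60.0) <= 0.1])

    def test_false_positive_rate_monotone_in_threshold(self, bg):
        strict = DeltaParams(peak_threshold_sd=2.0)
        loose = DeltaParams(peak_threshold_sd=1.5)
        n_strict = len(detect_delta(_trace(bg, region=Region.MPFC), strict))
        n_loose = len(detect_delta(_trace(bg, region=Region.MPFC), loose))
        assert n_strict <= n_loose

    def test_polarity_restriction(self, bg):
        amp = self._amp_for_z(bg, 0.3, 4.0)
        x = _inject(bg, delta_template(0.3, self.fs), 60000, amp)
        pos = detect_delta(_trace(x, region=Region.MPFC), DeltaParams(polarity="POS"))
        neg = detect_delta(_trace(x, region=Region.MPFC), DeltaParams(polarity="NEG"))
        both = detect_delta(_trace(x, region=Region.MPFC), DeltaParams(polarity="BOTH"))
        assert len(both) == len(pos) + len(neg)
        assert (np.abs(pos.df["peak_s"] - 60.0) <= 0.02).any()


class TestSpindleDetector:
    fs = 1000.0

    @pytest.fixture(scope="class")
    @staticmethod
    def bg():
        rng = np.random.default_rng(7)
        return rng.standard_normal(120000) * 8.0

    def _amp_for_z(self, bg, dur, target):
        from hcsleep.synthetic import _envelope_for_kind, _template_gain

        env = _envelope_for_kind(EventKind.SPINDLE, bg, self.fs)
        gain = _template_gain(EventKind.SPINDLE, dur, self.fs)
        return float(np.sqrt(target * env.std() / gain))

    def test_injected_spindle_detected(self, bg):
        amp = self._amp_for_z(bg, 0.8, 8.0)
        x = _inject(bg, spindle_template(0.8, self.fs), 60000, amp)
        events = detect_spindles(_trace(x, region=Region.MPFC))
        near = events.df[np.abs(events.df["peak_s"] - 60.0) <= 0.1]
        assert len(near) == 1

    def test_short_spindle_rejected(self, bg):
        """400 ms of high spindle-band power fails the >500 ms sustain."""
        amp = self._amp_for_z(bg, 0.4, 10.0)
        x = _inject(bg, spindle_template(0.4, self.fs), 60000, amp)
        events = detect_spindles(_trace(x, region=Region.MPFC))
        assert not len(events.df[np.abs(events.df["peak_s"] - 60.0) <= 0.2])

    def test_weak_spindle_rejected_by_peak_threshold(self, bg):
        """An 800 ms burst peaking at only 3 SD fails the 5 SD peak rule."""
        amp = self._amp_for_z(bg, 0.8, 3.0)
        x = _inject(bg, spindle_template(0.8, self.fs), 60000, amp)
        events = detect_spindles(_trace(x, region=Region.MPFC))
        assert not len(events.df[np.abs(events.df["peak_s"] - 60.0) <= 0.2])


class TestOracleEquivalence:
    """Detectors must equal a naive sample-scan on short random traces."""

    def _compare_ripples(self, x, fs):
        trace = _trace(x, fs)
        params = RippleParams()
        got = detect_ripples(trace, params).df
        z = normalized_envelope(trace, params.band, "lowpass", params.envelope_lowpass_hz)
        expected = scan_threshold_events(
            z, fs, params.boundary_threshold_sd, params.peak_threshold_sd,
            params.min_dur_ms, params.max_dur_ms, True,
        )
        assert len(got) == len(expected)
        for row, (s, p, e, pz) in zip(got.itertuples(), expected):
            assert row.start_s == pytest.approx(s)
            assert row.peak_s == pytest.approx(p)
            assert row.end_s == pytest.approx(e)
            assert row.peak_z == pytest.approx(pz)

    def _compare_deltas(self, x, fs):
        trace = _trace(x, fs, region=Region.MPFC)
        params = DeltaParams()
        got = detect_delta(trace, params).df
        sos = _bandpass_sos(params.band, fs, 2)
        filt = sg.sosfiltfilt(sos, x)
        z = (filt - filt.mean()) / filt.std()
        expected = scan_halfwave_events(
            z, fs, params.peak_threshold_sd, params.min_dur_ms,
            params.max_dur_ms, params.polarity,
        )
        assert len(got) == len(expected)
        for row, (s, p, e, pz) in zip(got.itertuples(), expected):
            assert row.peak_s == pytest.approx(p)
            assert row.peak_z == pytest.approx(pz)

    def test_random_traces_match_oracle(self):
        rng = np.random.default_rng(42)
        fs = 1000.0
        for i in range(100):
            n = int(rng.uniform(4.0, 8.0) * fs)
            x = rng.standard_normal(n) * 10.0
            # occasionally add bursts so some traces contain events
            if i % 2 == 0:
                tpl = ripple_template(rng.uniform(0.04, 0.12), fs)
                c = int(rng.uniform(0.3, 0.7) * n)
                x = _inject(x, tpl, c, rng.uniform(20, 60))
            self._compare_ripples(x, fs)
            self._compare_deltas(x, fs)

    def test_spindle_runs_match_oracle(self):
        rng = np.random.default_rng(43)
        fs = 1000.0
        params = SpindleParams(peak_time="ARGMAX")
        for i in range(50):
            n = int(rng.uniform(5.0, 10.0) * fs)
            x = rng.standard_normal(n) * 5.0
            if i % 2 == 0:
                tpl = spindle_template(rng.uniform(0.6, 1.2), fs)
                x = _inject(x, tpl, n // 2, rng.uniform(30, 80))
            trace = _trace(x, fs, region=Region.MPFC)
            got = detect_spindles(trace, params).df
            z = normalized_envelope(trace, params.band, "gaussian",
                                    params.smoothing_ms / 1000.0)
            expected = scan_threshold_events(
                z, fs, params.sustain_threshold_sd, params.peak_threshold_sd,
                params.min_dur_ms, params.max_dur_ms, False,
            )
            assert len(got) == len(expected)
            for row, (s, p, e, pz) in zip(got.itertuples(), expected):
                assert row.start_s == pytest.approx(s)
                assert row.peak_s == pytest.approx(p)


class TestSleepRestriction:
    def test_all_wake_empties_table(self, std_session):
        _, _, truth = std_session
        hyp = Hypnogram(stages=[Stage.WAKE] * 450, epoch_length_s=4.0)
        out = restrict_to_sleep(truth.true_events, hyp, {Stage.NREM})
        assert len(out) == 0

    def test_full_stage_set_is_identity(self, std_session):
        _, _, truth = std_session
        out = restrict_to_sleep(
            truth.true_events, truth.hypnogram,
            {Stage.WAKE, Stage.NREM, Stage.REM},
        )
        assert len(out) == len(truth.true_events)

    def test_nrem_only_truth_unchanged(self, std_session):
        _, _, truth = std_session
        out = restrict_to_sleep(truth.true_events, truth.hypnogram, {Stage.NREM})
        assert len(out) == len(truth.true_events)

    def test_event_outside_span_rejected(self, std_session):
        _, _, truth = std_session
        hyp = Hypnogram(stages=[Stage.NREM] * 10, epoch_length_s=4.0)
        with pytest.raises(ValidationError):
            restrict_to_sleep(truth.true_events, hyp)


class TestEventRates:
    def test_incidence_arithmetic(self, std_session):
        _, _, truth = std_session
        hyp = truth.hypnogram
        rates = event_rates(truth.true_events, hyp, {Stage.NREM})
        minutes = hyp.minutes_in({Stage.NREM})
        for _, row in rates.iterrows():
            assert row["incidence_per_min"] == pytest.approx(row["count"] / minutes)
        total = rates["count"].sum()
        assert rates["density_fraction"].sum() == pytest.approx(1.0)
        assert total == len(truth.true_events)

    def test_empty_table_flagged(self):
        from hcsleep.core import EventTable

        hyp = Hypnogram(stages=[Stage.NREM] * 150, epoch_length_s=4.0)
        rates = event_rates(EventTable(), hyp)
        assert (rates["incidence_per_min"] == 0).all()
        assert rates["mean_peak_z"].isna().all()

    def test_zero_sleep_guard(self, std_session):
        _, _, truth = std_session
        hyp = Hypnogram(stages=[Stage.WAKE] * 450, epoch_length_s=4.0)
        with pytest.raises(ZeroDivisionError):
            event_rates(truth.true_events, hyp, {Stage.NREM})


@settings(max_examples=25, deadline=None)
@given(st.floats(min_value=1.5, max_value=6.0))
def test_run_extraction_monotone_in_threshold(threshold):
    """Raising the boundary threshold never lengthens or adds runs."""
    rng = np.random.default_rng(99)
    z = rng.standard_normal(5000)
    lo = _threshold_runs(z >= threshold - 0.5)
    hi = _threshold_runs(z >= threshold)
    assert len(hi) <= len(lo)
    total = lambda runs: sum(e - s + 1 for s, e in runs)
    assert total(hi) <= total(lo)
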