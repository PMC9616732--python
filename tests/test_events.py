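import numpy as np
import pandas as pd
import pytest

from spindletopo.events import (DetectionParams, bandpass, bandpass_array,
                                characterize, circular_distance_deg,
                                detect_slow_oscillations, detect_spindles,
                                spindle_envelope, spindle_so_phase,
                                split_by_coupling)
from spindletopo.io_core import ArtifactMask, Hypnogram, Recording
from spindletopo.synthetic import score_detection

FS = 200.0


def _sine(freq, seconds=20.0, amp=1.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_sinusoid_preserved_and_unshifted(self):
        x = _sine(13.0, amp=5.0)
        rec = Recording(x[None], FS, ["a"])
        out = bandpass(rec, (12.0, 15.0)).signal[0]
        core = slice(int(2 * FS), int(18 * FS))
        assert np.abs(out[core]).max() == pytest.approx(5.0, rel=0.05)
        # zero-phase: peak positions unchanged
        xc = np.correlate(out[core], x[core], "full")
        lag = xc.argmax() - (len(x[core]) - 1)
        assert lag == 0

    def test_stopband_attenuation_matches_filter_oracle(self):
        from scipy.signal import butter, sosfreqz
        x = _sine(5.0, amp=1.0)
        out = bandpass_array(x, (12.0, 15.0), FS)
        core = slice(int(5 * FS), int(15 * FS))
        residual = np.abs(out[core]).max()
        sos = butter(4, (12.0, 15.0), btype="bandpass", fs=FS, output="sos")
        _, h = sosfreqz(sos, worN=[5.0], fs=FS)
        # two-pass filtering squares the magnitude response
        assert residual < 0.01
        assert residual == pytest.approx(np.abs(h[0]) ** 2, rel=0.5)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass_array(_sine(5.0), (10.0, 120.0), FS)


class TestSpindleEnvelope:
    def test_constant_sinusoid_envelope_is_amplitude(self):
        env = spindle_envelope(_sine(13.0, amp=2.0), FS)
        core = slice(int(2 * FS), int(18 * FS))
        np.testing.assert_allclose(env[core], 2.0, rtol=0.02)

    def test_zero_signal_zero_envelope(self):
        assert spindle_envelope(np.zeros(4000), FS).max() == 0.0

    def test_burst_envelope_peak_near_window_center(self):
        t = np.arange(4000) / FS
        center = 10.0
        env_true = np.exp(-((t - center) ** 2) / (2 * 0.2 ** 2))
        x = env_true * np.cos(2 * np.pi * 13.0 * (t - center))
        env = spindle_envelope(x, FS)
        assert abs(env.argmax() / FS - center) <= 0.025


def _nrem_setup(n_samples):
    n_epochs = int(np.ceil(n_samples / FS / 30))
    return Hypnogram(["N2"] * n_epochs), ArtifactMask([])


class TestDetectSpindles:
    def test_duration_criterion_separates_short_and_long_bursts(self):
        # deterministic amplitude-modulated 13 Hz carrier: 0.25 s amplitude
        # bumps are too brief to satisfy "more than 0.5 s", a 1 s bump of
        # the same height is detected
        t = np.arange(int(60 * FS)) / FS
        amplitude = np.ones(t.size)
        for center in (15.0, 30.0, 45.0):
            amplitude[np.abs(t - center) < 0.125] = 3.0
        amplitude[np.abs(t - 52.0) < 0.5] = 3.0
        x = amplitude * np.cos(2 * np.pi * 13 * t)
        hyp, art = _nrem_setup(t.size)
        events = detect_spindles(Recording(x[None], FS, ["a"]), hyp, art)
        for center in (15.0, 30.0, 45.0):
            sel = (events["onset_s"] < center) & (events["offset_s"] > center)
            assert not sel.any()
        sel = (events["onset_s"] < 52.0) & (events["offset_s"] > 52.0)
        assert sel.sum() == 1

    def test_amplitude_scaling_equivariance(self, strong_participant):
        _, bundle, _ = strong_participant
        rec = bundle.sleep
        small = Recording(rec.signal[:3], rec.fs, rec.channel_labels[:3])
        big = Recording(10.0 * small.signal, rec.fs, small.channel_labels)
        ev1 = detect_spindles(small, bundle.hypnogram, bundle.artifacts)
        ev2 = detect_spindles(big, bundle.hypnogram, bundle.artifacts)
        pd.testing.assert_frame_equal(
            ev1.drop(columns="amplitude_uV"),
            ev2.drop(columns="amplitude_uV"))
        np.testing.assert_allclose(ev2["amplitude_uV"],
                                   10.0 * ev1["amplitude_uV"], rtol=1e-9)

    def test_durations_within_bounds(self, strong_participant):
        _, bundle, _ = strong_participant
        ev = detect_spindles(bundle.sleep, bundle.hypnogram,
                             bundle.artifacts)
        assert (ev["duration_s"] > 0.5).all()
        assert (ev["duration_s"] < 3.0).all()

    def test_planted_bursts_recovered(self, strong_participant):
        _, bundle, truth = strong_participant
        ev = detect_spindles(bundle.sleep, bundle.hypnogram,
                             bundle.artifacts)
        score = score_detection(ev, truth.events, "spindle", 0.5)
        assert score["recall"] > 0.85

    def test_no_nrem_raises(self):
        rec = Recording(np.random.default_rng(0).normal(size=(1, 12000)),
                        FS, ["a"])
        hyp = Hypnogram(["REM", "REM"])
        with pytest.raises(ValueError, match="NREM"):
            detect_spindles(rec, hyp, ArtifactMask([]))


class TestDetectSlowOscillations:
    def test_equal_amplitude_population_yields_nothing(self):
        # every candidate identical -> none exceeds mean + 1.25*SD
        # (zero-phase filter transients at the recording edges are the
        # only place an event could appear, so assert on the interior)
        x = _sine(0.75, seconds=240.0, amp=30.0)
        hyp, art = _nrem_setup(x.size)
        ev = detect_slow_oscillations(Recording(x[None], FS, ["a"]), hyp,
                                      art)
        interior = ev[(ev["onset_s"] > 10.0) & (ev["offset_s"] < 230.0)]
        assert len(interior) == 0

    def test_long_half_wave_rejected_by_duration(self):
        # 0.4 Hz cycle lasts 2.5 s, outside the 0.8-2 s window
        rng = np.random.default_rng(1)
        x = _sine(0.4, seconds=120.0, amp=50.0)
        x += 2.0 * rng.standard_normal(x.size)
        hyp, art = _nrem_setup(x.size)
        ev = detect_slow_oscillations(Recording(x[None], FS, ["a"]), hyp,
                                      art)
        assert (ev["duration_s"] <= 2.0).all() if len(ev) else True

    def test_amplitude_scaling_equivariance(self, strong_participant):
        _, bundle, _ = strong_participant
        rec = bundle.sleep
        small = Recording(rec.signal[:3], rec.fs, rec.channel_labels[:3])
        big = Recording(7.0 * small.signal, rec.fs, small.channel_labels)
        ev1 = detect_slow_oscillations(small, bundle.hypnogram,
                                       bundle.artifacts)
        ev2 = detect_slow_oscillations(big, bundle.hypnogram,
                                       bundle.artifacts)
        pd.testing.assert_frame_equal(
            ev1.drop(columns="amplitude_uV"),
            ev2.drop(columns="amplitude_uV"))
        np.testing.assert_allclose(ev2["amplitude_uV"],
                                   7.0 * ev1["amplitude_uV"], rtol=1e-9)

    def test_durations_within_bounds_and_recall(self, strong_participant):
        _, bundle, truth = strong_participant
        ev = detect_slow_oscillations(bundle.sleep, bundle.hypnogram,
                                      bundle.artifacts)
        assert (ev["duration_s"] >= 0.8).all()
        assert (ev["duration_s"] <= 2.0).all()
        score = score_detection(ev, truth.events, "so", 0.5)
        assert score["recall"] > 0.8


class TestCharacterize:
    def test_density_is_count_over_minutes(self, strong_participant):
        _, bundle, _ = strong_participant
        ev = detect_spindles(bundle.sleep, bundle.hypnogram,
                             bundle.artifacts)
        topo = characterize(ev, bundle.hypnogram, bundle.artifacts,
                            bundle.sleep.fs, bundle.sleep.n_samples,
                            bundle.sleep.channel_labels)
        # exact conservation per channel: density * minutes == count
        back = topo.table["density_per_min"] * topo.nrem_minutes
        np.testing.assert_allclose(back, topo.table["n_events"], atol=1e-9)

    def test_no_events_gives_zero_density_missing_amplitude(self):
        from spindletopo.events import _empty_events
        hyp = Hypnogram(["N2"] * 4)
        topo = characterize(_empty_events(), hyp, ArtifactMask([]), FS,
                            int(120 * FS), ["a", "b"])
        assert (topo.table["density_per_min"] == 0).all()
        assert topo.table["amplitude_uV"].isna().all()

    def test_mixed_kinds_rejected(self):
        ev = pd.DataFrame({"kind": ["spindle", "so"], "channel": ["a", "a"],
                           "amplitude_uV": [1, 1], "duration_s": [1, 1]})
        hyp = Hypnogram(["N2"] * 4)
        with pytest.raises(ValueError, match="mixed"):
            characterize(ev, hyp, ArtifactMask([]), FS, int(120 * FS),
                         ["a"])


class TestCoupling:
    def test_planted_up_state_phase_recovered(self, strong_participant):
        _, bundle, truth = strong_participant
        ev = detect_spindles(bundle.sleep, bundle.hypnogram,
                             bundle.artifacts)
        ev = spindle_so_phase(bundle.sleep, ev)
        from spindletopo.circular import circ_mean_deg
        got = circ_mean_deg(ev["so_phase_deg"])
        want = circ_mean_deg(truth.events.query("kind == 'spindle'")
                             ["so_phase_deg"])
        diff = abs((got - want + 180) % 360 - 180)
        assert diff < 15.0

    def test_split_by_coupling_simple(self):
        ev = pd.DataFrame({
            "channel": ["a"] * 2, "onset_s": [1.0, 5.0],
            "so_phase_deg": [10.0, 170.0],
        })
        hi, lo = split_by_coupling(ev)
        assert list(hi["so_phase_deg"]) == [10.0]
        assert list(lo["so_phase_deg"]) == [170.0]

    def test_split_symmetry(self):
        ev = pd.DataFrame({
            "channel": ["a"] * 4, "onset_s": [1.0, 5.0, 9.0, 13.0],
            "so_phase_deg": [-5.0, 5.0, 175.0, -175.0],
        })
        hi, lo = split_by_coupling(ev)
        assert sorted(hi["so_phase_deg"]) == [-5.0, 5.0]
        assert sorted(lo["so_phase_deg"]) == [-175.0, 175.0]

    def test_odd_count_extra_goes_to_higher(self):
        ev = pd.DataFrame({
            "channel": ["a"] * 3, "onset_s": [1.0, 5.0, 9.0],
            "so_phase_deg": [0.0, 90.0, 180.0],
        })
        hi, lo = split_by_coupling(ev)
        assert len(hi) == 2 and len(lo) == 1

    def test_von_mises_sample_orderings(self):
        rng = np.random.default_rng(0)
        phases = np.degrees(rng.vonmises(0.0, 5.0, size=100))
        ev = pd.DataFrame({"channel": ["a"] * 100,
                           "onset_s": np.arange(100.0),
                           "so_phase_deg": phases})
        hi, lo = split_by_coupling(ev)
        assert (circular_distance_deg(hi["so_phase_deg"]).mean()
                < circular_distance_deg(lo["so_phase_deg"]).mean())

    def test_circular_distance_wraps(self):
        np.testing.assert_allclose(
            circular_distance_deg([0.0, 180.0, -180.0, 350.0, -350.0]),
            [0.0, 180.0, 180.0, 10.0, 10.0])
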