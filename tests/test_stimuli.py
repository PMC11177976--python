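import numpy as np
import pytest

from chirpic import (
    ChirpTrainSpec,
    Waveform,
    apply_ramp,
    chirp_fundamental,
    make_chirp,
    make_chirp_sequence,
    make_click_train,
    make_sam_noise,
    make_tone,
    set_level,
)
from chirpic.stimuli import P_REF

FS = 100_000.0


class TestRamp:
    def test_zero_ramp_is_identity(self):
        w = Waveform(np.ones(1000), FS)
        assert np.array_equal(apply_ramp(w, 0.0).samples, w.samples)

    def test_endpoints_zero_and_midpoint_half(self):
        w = Waveform(np.ones(2000), FS)
        out = apply_ramp(w, 5e-3)  # 500-sample ramp
        assert out.samples[0] == 0.0
        assert out.samples[-1] == pytest.approx(0.0, abs=1e-10)
        # raised cosine 0.5*(1-cos(pi t/T)) = 0.5 at t = T/2
        assert out.samples[250] == pytest.approx(0.5, abs=0.01)
        # interior untouched
        assert np.all(out.samples[500:1500] == 1.0)

    def test_ramp_preserves_duration(self):
        w = Waveform(np.ones(1234), FS)
        assert apply_ramp(w, 3e-3).n == 1234

    def test_too_long_ramp_rejected(self):
        w = Waveform(np.ones(100), FS)
        with pytest.raises(ValueError):
            apply_ramp(w, 0.5)


class TestLevel:
    def test_known_sine_measures_60_db(self):
        t = np.arange(2000) / FS
        w = Waveform(np.sqrt(2) * 0.02 * np.sin(2 * np.pi * 1000 * t), FS)
        assert w.level() == pytest.approx(60.0, abs=0.01)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        w = Waveform(rng.standard_normal(5000), FS)
        for target in (10.0, 47.3, 70.0):
            assert set_level(w, target).level() == pytest.approx(target, abs=0.01)

    def test_plus_20_db_multiplies_by_10(self):
        w = Waveform(np.sin(np.arange(1000)), FS)
        a = set_level(w, 50.0).samples
        b = set_level(w, 70.0).samples
        assert np.allclose(b, 10.0 * a)

    def test_zero_waveform_rejected(self):
        with pytest.raises(ValueError):
            set_level(Waveform(np.zeros(100), FS), 60.0)


class TestTone:
    def test_sample_count_and_level(self):
        w = make_tone(1000.0, dur=0.2, level=70.0, fs=FS)
        assert w.n == 20_000
        assert w.rms() == pytest.approx(P_REF * 10 ** 3.5, rel=1e-6)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_tone(60_000.0, fs=FS)


class TestSamNoise:
    def test_overall_level_is_70_db(self):
        w = make_sam_noise(100.0, 1.0, (100.0, 10_000.0), 30.0, dur=1.0, fs=FS, seed=0)
        assert w.level() == pytest.approx(70.0, abs=0.1)

    def test_unmodulated_matches_carrier(self):
        w0 = make_sam_noise(0.0, 1.0, dur=0.3, fs=FS, seed=4)
        w1 = make_sam_noise(100.0, 0.0, dur=0.3, fs=FS, seed=4)
        assert np.allclose(w0.samples, w1.samples)

    def test_envelope_periodicity(self):
        fm, dur = 100.0, 1.0
        w = make_sam_noise(fm, 1.0, dur=dur, fs=FS, seed=1)
        env = np.abs(w.samples)
        # count envelope minima via the modulator's zero crossings: the squared
        # signal's energy in 10-ms bins should oscillate with 100 periods
        bins = env.reshape(int(dur * fm), -1) ** 2
        per_cycle = bins.sum(axis=1)
        assert per_cycle.std() / per_cycle.mean() < 0.5  # stable cycle energy

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            make_sam_noise(100.0, 1.5, fs=FS)


class TestClickTrain:
    def test_click_count_and_sign(self):
        w = make_click_train(200.0, dur=1.0, fs=FS)
        onsets = np.flatnonzero(np.diff((w.samples < 0).astype(int)) == 1) + 1
        n_clicks = onsets.size + int(w.samples[0] < 0)
        assert n_clicks == 200
        assert np.all(w.samples <= 0)

    def test_peak_equivalent_level(self):
        w = make_click_train(100.0, level=130.0, dur=0.1, fs=FS)
        assert np.abs(w.samples).max() == pytest.approx(
            np.sqrt(2) * P_REF * 10 ** 6.5, rel=1e-9
        )

    def test_overlapping_clicks_rejected(self):
        with pytest.raises(ValueError):
            make_click_train(5000.0, click_dur=3e-4, fs=FS)


class TestChirp:
    # fundamental frequencies solving (f_top - F0) F0 = |v| 1e6 at f_top 16 kHz
    @pytest.mark.parametrize(
        "velocity,f0",
        [(0.40, 25.04), (0.80, 50.16), (1.59, 100.0), (3.16, 200.0),
         (6.24, 400.0), (9.24, 600.0)],
    )
    def test_duration_law(self, velocity, f0):
        assert chirp_fundamental(velocity) == pytest.approx(f0, abs=0.2)
        w = make_chirp(velocity, fs=FS)
        assert w.duration == pytest.approx(1.0 / f0, abs=1.01 / FS)

    def test_reference_chirp_duration_and_level(self):
        w = make_chirp(6.24, fs=FS)
        assert w.duration * 1e3 == pytest.approx(2.5, abs=1e-6)
        assert w.level() == pytest.approx(65.0, abs=1e-6)

    def test_level_formula(self):
        # T = 10 ms at 1.59 kHz/ms: level = 65 - 10 log10(10/2.5)
        w = make_chirp(1.59, fs=FS)
        assert w.level() == pytest.approx(65.0 - 10 * np.log10(4.0), abs=1e-6)

    def test_energy_equal_across_velocities(self):
        spec = ChirpTrainSpec()
        energies = [
            np.sum(make_chirp(v, spec, FS).samples ** 2) / FS
            for v in spec.velocities
        ]
        assert max(energies) / min(energies) - 1 < 0.01

    def test_downward_sweeps_downward(self):
        up = make_chirp(1.59, fs=FS)
        down = make_chirp(-1.59, fs=FS)
        # instantaneous frequency from the analytic-signal phase slope
        from scipy.signal import hilbert

        def mean_slope(w):
            phase = np.unwrap(np.angle(hilbert(w.samples)))
            mid = slice(w.n // 4, 3 * w.n // 4)
            return np.polyfit(np.arange(w.n)[mid] / FS, phase[mid], 1)[0]

        assert mean_slope(up) > 0 or mean_slope(down) < mean_slope(up)

    def test_unreachable_velocity_rejected(self):
        with pytest.raises(ValueError):
            make_chirp(100.0, fs=FS)


class TestChirpSequence:
    def test_event_counts_gaps_and_determinism(self):
        spec = ChirpTrainSpec(n_reps=3, seed=9)
        wave, events = make_chirp_sequence(spec, FS)
        assert len(events) == 12 * 3
        for v in spec.velocities:
            assert len(events.for_velocity(v)) == 3
        # events are time ordered and non-overlapping, with gaps in range
        prev_off = 0.0
        for e in events:
            gap = e.onset - prev_off
            assert 0.040 - 1e-9 <= gap <= 0.060 + 1e-9
            assert e.offset > e.onset
            prev_off = e.offset
        wave2, events2 = make_chirp_sequence(spec, FS)
        assert np.array_equal(wave.samples, wave2.samples)
        assert [e.onset for e in events] == [e.onset for e in events2]

    def test_waveform_consistent_with_log(self):
        spec = ChirpTrainSpec(n_reps=2, seed=5)
        wave, events = make_chirp_sequence(spec, FS)
        for e in list(events)[:6]:
            i0, i1 = int(e.onset * FS), int(e.offset * FS)
            assert np.any(wave.samples[i0:i1] != 0)
            # silence just before onset
            assert np.all(wave.samples[max(i0 - 50, 0) : i0] == 0)

    def test_asymmetric_velocities_rejected(self):
        with pytest.raises(ValueError):
            ChirpTrainSpec(velocities=(1.0, 2.0, -1.0))
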