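"""Calibrated acoustic stimulus synthesis.

All stimuli are produced as sound-pressure waveforms in pascals at a known
sample rate, so that levels can be stated in dB SPL re 20 µPa.  The battery
covers the four stimulus families used to characterize the model: pure tones
(response maps), sinusoidally amplitude-modulated noise (modulation transfer
functions), aperiodic linear-chirp sequences (rate-velocity functions), and
rarefaction click trains (entrainment).

Chirps are synthesized directly as linear-frequency cosine sweeps.  Each chirp
corresponds to one fundamental period of a Schroeder-phase harmonic complex:
a sweep from the fundamental F0 up to a fixed top frequency ``f_top`` whose
duration is one fundamental period, 1/F0.  Given a signed sweep velocity v
(kHz/ms, i.e. |v|·1e6 Hz/s), F0 is the smaller root of

    (f_top - F0) * F0 = |v| * 1e6

so that (f_top - F0)/T = |v|·1e6 with T = 1/F0.  Chirp level is scaled as
``ref_level - 10*log10(T/T_ref)`` which makes the energy ∫p²dt identical
across velocities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

P_REF = 20e-6  # reference pressure, Pa (0 dB SPL)

#: the standard set of signed chirp velocities, kHz/ms
DEFAULT_VELOCITIES: tuple[float, ...] = (
    -9.24, -6.24, -3.16, -1.59, -0.80, -0.40,
    0.40, 0.80, 1.59, 3.16, 6.24, 9.24,
)

DEFAULT_FS = 100_000.0


@dataclass(frozen=True)
class Waveform:
    """A calibrated pressure time series.

    Attributes
    ----------
    samples : np.ndarray
        Sound pressure in Pa.
    fs : float
        Sample rate in Hz.
    t0 : float
        Start time in seconds (bookkeeping only).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level(self) -> float:
        """Overall level in dB SPL (RMS re 20 µPa)."""
        r = self.rms()
        if r == 0:
            raise ValueError("level undefined for an all-zero waveform")
        return 20.0 * np.log10(r / P_REF)


@dataclass(frozen=True)
class ChirpEvent:
    onset: float
    offset: float
    velocity: float


@dataclass
class EventLog:
    """Time-ordered record of chirp presentations within a sequence."""

    events: list[ChirpEvent] = field(default_factory=list)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def velocities(self) -> np.ndarray:
        return np.array(sorted({e.velocity for e in self.events}))

    def for_velocity(self, velocity: float) -> list[ChirpEvent]:
        return [e for e in self.events if e.velocity == velocity]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "offset_s": [e.offset for e in self.events],
                "velocity_khz_per_ms": [e.velocity for e in self.events],
            }
        ).to_csv(path, index=False, float_format="%.9g")


@dataclass(frozen=True)
class ChirpTrainSpec:
    """Specification of the randomized aperiodic chirp sequence."""

    velocities: tuple[float, ...] = DEFAULT_VELOCITIES
    n_reps: int = 42
    gap_range: tuple[float, float] = (0.040, 0.060)
    ref_level: float = 65.0  # dB SPL, at the reference duration
    T_ref: float = 2.5e-3  # s, duration of the +/-6.24 kHz/ms chirp
    f_top: float = 16_000.0  # Hz, upper sweep frequency
    seed: int = 0

    def __post_init__(self):
        vset = set(self.velocities)
        if any(-v not in vset for v in vset) or 0.0 in vset:
            raise ValueError("velocities must be nonzero and symmetric about 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.gap_range[0] <= self.gap_range[1]:
            raise ValueError("gap_range must be (low, high) with low <= high")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive")


def apply_ramp(w: Waveform, ramp_dur: float) -> Waveform:
    """Apply raised-cosine (hann-shaped) onset/offset ramps of ``ramp_dur`` s."""
    if ramp_dur < 0:
        raise ValueError("ramp_dur must be nonnegative")
    if ramp_dur == 0:
        return w
    n_ramp = int(round(ramp_dur * w.fs))
    if 2 * n_ramp > w.n:
        raise ValueError(
            f"ramp of {ramp_dur} s does not fit twice in a {w.duration} s waveform"
        )
    if n_ramp == 0:
        return w
    # 0.5*(1 - cos(pi*t/ramp_dur)) sampled so the first sample is exactly 0
    t = np.arange(n_ramp) / w.fs
    env = 0.5 * (1.0 - np.cos(np.pi * t / ramp_dur))
    samples = w.samples.copy()
    samples[:n_ramp] *= env
    samples[-n_ramp:] *= env[::-1]
    return replace(w, samples=samples)


def set_level(w: Waveform, level: float) -> Waveform:
    """Scale a waveform so its overall RMS equals ``level`` dB SPL re 20 µPa."""
    r = w.rms()
    if r == 0:
        raise ValueError("cannot set the level of an all-zero waveform")
    target = P_REF * 10.0 ** (level / 20.0)
    return replace(w, samples=w.samples * (target / r))


def make_tone(
    freq: float, dur: float = 0.2, level: float = 70.0,
    fs: float = DEFAULT_FS, ramp_dur: float = 0.010,
) -> Waveform:
    """A ramped, level-calibrated pure tone."""
    if freq >= fs / 2:
        raise ValueError(f"tone frequency {freq} Hz is at or above Nyquist ({fs/2} Hz)")
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    w = Waveform(np.sin(2 * np.pi * freq * t), fs)
    return set_level(apply_ramp(w, ramp_dur), level)


def _band_noise(band: tuple[float, float], n: int, fs: float, rng) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` by FFT brick-wall filtering."""
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    return np.fft.irfft(spec, n)


def make_sam_noise(
    fm: float,
    mod_depth: float = 1.0,
    band: tuple[float, float] = (100.0, 10_000.0),
    spectrum_level: float = 30.0,
    dur: float = 1.0,
    fs: float = DEFAULT_FS,
    seed: int | None = 0,
    ramp_dur: float = 0.050,
) -> Waveform:
    """Sinusoidally amplitude-modulated band-limited Gaussian noise.

    The carrier is calibrated to ``spectrum_level`` dB SPL per Hz; after
    modulation and ramping the waveform is rescaled to the carrier's nominal
    overall level, ``spectrum_level + 10*log10(bandwidth)``, so modulated and
    unmodulated stimuli are presented at the same overall level.  With
    ``fm == 0`` or ``mod_depth == 0`` the unmodulated reference is returned.
    """
    if not 0.0 <= mod_depth <= 1.0:
        raise ValueError(f"mod_depth must be in [0, 1], got {mod_depth}")
    if not (0 < band[0] < band[1] < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, fs/2)")
    n = int(round(dur * fs))
    rng = np.random.default_rng(seed)
    x = _band_noise(band, n, fs, rng)
    overall = spectrum_level + 10.0 * np.log10(band[1] - band[0])
    if fm > 0 and mod_depth > 0:
        t = np.arange(n) / fs
        x = x * (1.0 + mod_depth * np.sin(2 * np.pi * fm * t))
    w = apply_ramp(Waveform(x, fs), ramp_dur)
    return set_level(w, overall)


def make_click_train(
    rate: float,
    click_dur: float = 1e-4,
    level: float = 130.0,
    dur: float = 1.0,
    fs: float = DEFAULT_FS,
) -> Waveform:
    """Periodic rarefaction (negative-going) rectangular clicks.

    ``level`` is peak-equivalent SPL: the peak pressure magnitude equals the
    peak of a sinusoid with that RMS level, sqrt(2)*20e-6*10**(level/20) Pa.
    """
    if rate * click_dur >= 1.0:
        raise ValueError(
            f"clicks of {click_dur} s overlap at {rate} Hz (duty cycle >= 1)"
        )
    n = int(round(dur * fs))
    n_click = max(1, int(round(click_dur * fs)))
    peak = np.sqrt(2.0) * P_REF * 10.0 ** (level / 20.0)
    samples = np.zeros(n)
    n_clicks = int(np.floor(dur * rate))
    for k in range(n_clicks):
        i = int(round(k / rate * fs))
        samples[i : i + n_click] = -peak
    return Waveform(samples, fs)


def chirp_fundamental(velocity: float, f_top: float = 16_000.0) -> float:
    """Solve (f_top - F0)*F0 = |velocity|*1e6 for the smaller root F0 (Hz)."""
    slope = abs(velocity) * 1e6  # Hz/s
    disc = f_top**2 - 4.0 * slope
    if disc <= 0:
        raise ValueError(
            f"no chirp fundamental exists for velocity {velocity} kHz/ms "
            f"with f_top = {f_top} Hz"
        )
    return (f_top - np.sqrt(disc)) / 2.0


def make_chirp(
    velocity: float, spec: ChirpTrainSpec | None = None, fs: float = DEFAULT_FS
) -> Waveform:
    """One aperiodic linear-frequency chirp at a signed velocity (kHz/ms).

    Sweeps from F0 to ``f_top`` (upward for velocity > 0, downward for < 0)
    over one fundamental period T = 1/F0, with raised-cosine ramps of 0.1·T
    and level ``ref_level - 10*log10(T/T_ref)`` dB SPL.
    """
    if spec is None:
        spec = ChirpTrainSpec()
    if velocity == 0:
        raise ValueError("chirp velocity must be nonzero")
    f0 = chirp_fundamental(velocity, spec.f_top)
    T = 1.0 / f0
    n = int(round(T * fs))
    t = np.arange(n) / fs
    slope = abs(velocity) * 1e6
    if velocity > 0:
        phase = 2 * np.pi * (f0 * t + 0.5 * slope * t**2)
    else:
        phase = 2 * np.pi * (spec.f_top * t - 0.5 * slope * t**2)
    w = apply_ramp(Waveform(np.cos(phase), fs), 0.1 * T)
    level = spec.ref_level - 10.0 * np.log10(T / spec.T_ref)
    return set_level(w, level)


def make_chirp_sequence(
    spec: ChirpTrainSpec, fs: float = DEFAULT_FS
) -> tuple[Waveform, EventLog]:
    """Randomized concatenation of all direction x velocity conditions.

    Each condition appears exactly ``spec.n_reps`` times in random order, with
    silent gaps drawn uniformly from ``spec.gap_range`` between chirp offsets
    and onsets (and before the first chirp).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = np.repeat(np.asarray(spec.velocities, dtype=float), spec.n_reps)
    rng.shuffle(conditions)
    chirps = {v: make_chirp(v, spec, fs) for v in spec.velocities}
    pieces: list[np.ndarray] = []
    events: list[ChirpEvent] = []
    t_samples = 0
    for v in conditions:
        gap = rng.uniform(*spec.gap_range)
        n_gap = int(round(gap * fs))
        pieces.append(np.zeros(n_gap))
        t_samples += n_gap
        c = chirps[v]
        events.append(ChirpEvent(t_samples / fs, (t_samples + c.n) / fs, float(v)))
        pieces.append(c.samples)
        t_samples += c.n
    # trailing pad so the response to the last chirp is fully contained
    pieces.append(np.zeros(int(round(0.030 * fs))))
    return Waveform(np.concatenate(pieces), fs), EventLog(events)


def write_wav(w: Waveform, path) -> None:
    """Export a waveform as 32-bit float WAV (samples in Pa) + sidecar JSON."""
    from scipy.io import wavfile

    wavfile.write(str(path), int(round(w.fs)), w.samples.astype(np.float32))
    meta = {
        "fs_hz": w.fs,
        "units": "Pa",
        "calibration": "sample value 1.0 = 1 Pa; 0 dB SPL = 20e-6 Pa RMS",
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
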