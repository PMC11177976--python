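"""Auditory-nerve front-end: waveform -> instantaneous discharge rate.

The downstream coincidence-detector stages consume instantaneous rate
functions λ(t) in spikes/s, the universal inter-stage currency.  This module
provides a pluggable backend registry (array-in/array-out adapter contract:
pressure waveform in Pa + sample rate + CF -> rate in spikes/s at the same
sample rate) and a built-in phenomenological surrogate for a
high-spontaneous-rate (HSR) fiber.

The surrogate chain, in order:

1. Level-dependent 4th-order gammatone bandpass at the characteristic
   frequency (cascade of four complex one-pole resonators, unity gain at CF).
   Base bandwidth follows the standard ERB formula; bandwidth broadens with
   stimulus peak level (doubling per ~20 dB above 60 dB peak SPL), emulating
   the broadened, faster-ringing cochlear filter at high levels.  Filter
   group delay ~3/(2πb) decreases with CF, emulating traveling-wave latency.
2. Half-wave rectification followed by broken-stick compression: linear below
   a 1-mPa knee, 0.25-power above it (linear near threshold, strongly
   compressive at moderate-to-high levels).
3. Saturating transduction ``s = c / (c + knee)`` with half-saturation at the
   knee, giving HSR-like thresholds near 0-10 dB SPL at CF.
4. Sharp low-pass (6th-order Chebyshev-II, stopband from 3.4 kHz): the
   inner-hair-cell membrane cut-off.  Fine structure survives at low CFs and
   is removed above ~3 kHz while envelope is preserved.
5. Subtractive rapid + short-term adaptation producing onset emphasis:
   rate = max(spont + drive * (s - β·A), 0), with A a 0.75/0.25 mixture of
   1-ms and 60-ms low-passed copies of s.  Sustained rate at CF saturation
   lands in the HSR range (~200-300 spikes/s) with onset peaks well above
   it; after strong drive the rate transiently dips below spontaneous
   (post-onset suppression), which deepens envelope coding.

Fiber-to-fiber variability is realized as independent additive band-limited
Gaussian noise on the deterministic rate; averaging n_fibers x n_reps
realizations shrinks the noise variance by that factor, mirroring the mean of
independent HSR fibers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from .stimuli import P_REF, Waveform

# surrogate constants (see module docstring and docs/methods.md)
KNEE_PA = 1e-3        # broken-stick knee (~31 dB SPL RMS for a tone)
COMPRESS_EXP = 0.25   # compressive exponent above the knee
LOWPASS_STOP_HZ = 3400.0  # IHC low-pass stopband edge
LOWPASS_ATTEN_DB = 40.0
BW_LEVEL_REF_DB = 60.0    # peak level where bandwidth broadening starts
BW_LEVEL_SLOPE_DB = 20.0  # dB of peak level per unit bandwidth increase
TAU_RAPID = 0.001     # rapid adaptation time constant, s
TAU_SHORT = 0.060     # short-term adaptation time constant, s
W_RAPID = 0.75        # weight of the rapid component
RATE_DRIVE = 2100.0   # driven-rate scale, spikes/s
BETA_ADAPT = 0.8      # subtractive adaptation strength
NOISE_FRAC = 0.25     # per-fiber noise std as a fraction of the rate
NOISE_FLOOR = 3.0     # per-fiber noise std floor, spikes/s
DEFAULT_SPONT = 60.0  # HSR spontaneous rate, spikes/s


@dataclass(frozen=True)
class RateFunction:
    """Instantaneous discharge rate λ(t) in spikes/s at sample rate fs."""

    lam: np.ndarray
    fs: float

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        if not np.all(np.isfinite(lam)):
            raise ValueError("rate function must be finite")
        if np.any(lam < 0):
            raise ValueError("rate function must be nonnegative")
        object.__setattr__(self, "lam", lam)

    @property
    def n(self) -> int:
        return self.lam.size

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class ANChannelSpec:
    """One auditory-nerve frequency channel as seen by the model.

    ``n_fibers`` independent fibers and ``n_reps`` repetitions are averaged
    into a single rate function.  ``seed=None`` yields the deterministic
    (noise-free) rate.
    """

    cf: float
    n_fibers: int = 10
    n_reps: int = 1
    spont: float = DEFAULT_SPONT
    seed: int | None = None

    def __post_init__(self):
        if self.cf <= 0:
            raise ValueError("cf must be positive")
        if self.n_fibers < 1 or self.n_reps < 1:
            raise ValueError("n_fibers and n_reps must be >= 1")
        if self.spont < 0:
            raise ValueError("spont must be nonnegative")


Backend = Callable[..., RateFunction]
_BACKENDS: dict[str, Backend] = {}


def register_backend(name: str, fn: Backend) -> None:
    """Register an AN backend: fn(w: Waveform, cf: float, spont: float) -> RateFunction."""
    _BACKENDS[name] = fn


def get_backend(name: str) -> Backend:
    try:
        return _BACKENDS[name]
    except KeyError:
        raise KeyError(
            f"unknown AN backend {name!r}; registered: {sorted(_BACKENDS)}"
        ) from None


def erb_bandwidth(cf: float) -> float:
    """Equivalent rectangular bandwidth (Hz) at a given CF (Glasberg-Moore)."""
    return 24.7 * (4.37 * cf / 1000.0 + 1.0)


def _onepole(x: np.ndarray, tau: float, fs: float) -> np.ndarray:
    a = 1.0 - np.exp(-1.0 / (tau * fs))
    return signal.lfilter([a], [1.0, -(1.0 - a)], x)


def gammatone_filter(
    x: np.ndarray, cf: float, fs: float, bw_scale: float = 1.0
) -> np.ndarray:
    """4th-order gammatone bandpass: cascade of complex one-pole resonators.

    Bandwidth is ``bw_scale`` times the standard 1.019*ERB(cf); gain is
    normalized to unity at CF.  Group delay at CF is ~3/(2π b), so higher
    CFs (and broader filters) respond earlier.
    """
    b = 1.019 * erb_bandwidth(cf) * bw_scale
    pole = np.exp(-2 * np.pi * b / fs) * np.exp(2j * np.pi * cf / fs)
    y = x.astype(complex)
    coef_b, coef_a = [1.0 - abs(pole)], [1.0, -pole]
    for _ in range(4):
        y = signal.lfilter(coef_b, coef_a, y)
    z_cf = np.exp(2j * np.pi * cf / fs)
    gain = abs(((1.0 - abs(pole)) / (1.0 - pole / z_cf)) ** 4)
    return np.real(y) / gain


def peak_level_db(w: Waveform) -> float:
    """Peak sound pressure level, dB re 20 µPa."""
    pk = float(np.max(np.abs(w.samples)))
    return 20.0 * np.log10(max(pk, P_REF) / P_REF)


def surrogate_backend(
    w: Waveform, cf: float, spont: float = DEFAULT_SPONT
) -> RateFunction:
    """Deterministic surrogate HSR-fiber rate function (see module docstring)."""
    if cf >= w.fs / 2:
        raise ValueError(f"cf {cf} Hz at or above Nyquist ({w.fs / 2} Hz)")
    bw_scale = 1.0 + max(0.0, peak_level_db(w) - BW_LEVEL_REF_DB) / BW_LEVEL_SLOPE_DB
    x = gammatone_filter(w.samples, cf, w.fs, bw_scale)
    v = np.maximum(x, 0.0)
    c = np.where(v <= KNEE_PA, v, KNEE_PA * (v / KNEE_PA) ** COMPRESS_EXP)
    s = c / (c + KNEE_PA)
    if LOWPASS_STOP_HZ < w.fs / 2:
        sos = signal.cheby2(6, LOWPASS_ATTEN_DB, LOWPASS_STOP_HZ, fs=w.fs, output="sos")
        s = np.maximum(signal.sosfilt(sos, s), 0.0)
    adapt = W_RAPID * _onepole(s, TAU_RAPID, w.fs) + (1.0 - W_RAPID) * _onepole(
        s, TAU_SHORT, w.fs
    )
    # adaptation may push the rate below spontaneous (post-onset suppression,
    # as in real fibers); only negative rates are clipped
    lam = spont + RATE_DRIVE * (s - BETA_ADAPT * adapt)
    return RateFunction(np.maximum(lam, 0.0), w.fs)


register_backend("surrogate", surrogate_backend)


def an_rate(w: Waveform, spec: ANChannelSpec, backend: str = "surrogate") -> RateFunction:
    """Mean rate function of ``n_fibers * n_reps`` independent fiber realizations.

    The backend supplies the deterministic rate for this channel; fiber
    independence is realized as additive band-limited Gaussian noise whose
    averaged standard deviation shrinks as 1/sqrt(n_fibers * n_reps).
    """
    fn = get_backend(backend)
    det = fn(w, spec.cf, spec.spont)
    if spec.seed is None:
        return det
    rng = np.random.default_rng(spec.seed)
    k = spec.n_fibers * spec.n_reps
    sd = (NOISE_FRAC * det.lam + NOISE_FLOOR) / np.sqrt(k)
    noise = rng.standard_normal(det.n) * sd
    sos = signal.butter(2, min(3000.0, 0.45 * w.fs), fs=w.fs, output="sos")
    noise = signal.sosfilt(sos, noise)
    return RateFunction(np.maximum(det.lam + noise, 0.0), det.fs)
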