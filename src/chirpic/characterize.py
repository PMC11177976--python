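"""Response characterization: response maps, MTFs, click MTFs, and RVFs.

Runs stimulus batteries through a configured model and reduces the stage rate
functions to the standard response curves:

* response map (RM): mean rate vs tone frequency at several sound levels,
  with the characteristic frequency estimated as the frequency excited above
  spontaneous rate at the lowest responsive level;
* noise MTF: mean rate vs modulation frequency of 100%-modulated SAM noise,
  classified as band-enhanced / band-suppressed / flat against the
  unmodulated reference, with best modulation frequency (BMF) when enhanced;
* click MTF: threshold-crossing counts of the rate function per click rate
  (entrainment measure, with a refractory lockout);
* rate-velocity function (RVF): mean rate vs signed chirp velocity, scored
  in a 15-ms window centered at the peak of the condition-averaged response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frontend import RateFunction
from .model import TwoStageModel
from .stimuli import (
    ChirpTrainSpec,
    EventLog,
    Waveform,
    make_click_train,
    make_sam_noise,
    make_tone,
)

_X_LABEL = {
    "RM-row": "frequency_hz",
    "MTF": "modulation_frequency_hz",
    "clickMTF": "click_rate_hz",
    "RVF": "velocity_khz_per_ms",
}

#: default modulation-frequency grid: 3 per octave over 2-500 Hz
def mtf_frequencies(lo: float = 2.0, hi: float = 500.0, per_octave: int = 3) -> np.ndarray:
    n = int(np.floor(per_octave * np.log2(hi / lo))) + 1
    return lo * 2.0 ** (np.arange(n) / per_octave)


def rm_frequencies(lo: float = 250.0, hi: float = 10_000.0, n: int = 30) -> np.ndarray:
    return np.geomspace(lo, hi, n)


RM_LEVELS = (10.0, 30.0, 50.0, 70.0)
CLICK_RATES = (2.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0)


@dataclass(frozen=True)
class ResponseCurve:
    """A labeled response curve: x-axis values vs mean rate (+/- spread)."""

    x: np.ndarray
    rate: np.ndarray
    spread: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _X_LABEL:
            raise ValueError(f"kind must be one of {sorted(_X_LABEL)}")
        for name in ("x", "rate", "spread"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.x.size == self.rate.size == self.spread.size):
            raise ValueError("x, rate and spread must have equal length")
        if np.any(self.rate < 0) or np.any(self.spread < 0):
            raise ValueError("rate and spread must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {_X_LABEL[self.kind]: self.x, "rate_sp_s": self.rate, "spread_sp_s": self.spread}
        )


@dataclass(frozen=True)
class MTFClassification:
    """MTF shape label; ``bmf`` is present iff the MTF is band-enhanced."""

    label: str  # band-enhanced | band-suppressed | flat | other
    bmf: float | None
    unmod_rate: float

    def __post_init__(self):
        if (self.label == "band-enhanced") != (self.bmf is not None):
            raise ValueError("bmf must be present iff label is band-enhanced")


def mean_rate(lam: RateFunction, t0: float = 0.0, t1: float | None = None) -> float:
    """Average of λ(t) over [t0, t1): (Σ λ·dt) / (t1 - t0)."""
    if t1 is None:
        t1 = lam.duration
    i0, i1 = int(round(t0 * lam.fs)), int(round(t1 * lam.fs))
    if not 0 <= i0 < i1 <= lam.n:
        raise ValueError(f"empty or out-of-range window [{t0}, {t1})")
    return float(np.sum(lam.lam[i0:i1]) / lam.fs / (t1 - t0))


def _spawn_seeds(seed: int | None, n: int) -> list[int | None]:
    if seed is None:
        return [None] * n
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def response_map(
    model: TwoStageModel,
    freqs=None,
    levels=RM_LEVELS,
    stage: str = "oct",
    dur: float = 0.2,
    fs: float = 100_000.0,
) -> tuple[list[ResponseCurve], float | None]:
    """Pure-tone response map and estimated CF.

    One curve per sound level (deterministic front-end).  CF is the frequency
    of maximal above-spontaneous excitation at the lowest level showing any;
    ``None`` if no tone excites the cell above spontaneous rate.
    """
    freqs = rm_frequencies() if freqs is None else np.asarray(freqs, dtype=float)
    if freqs.size == 0 or len(levels) == 0:
        raise ValueError("frequency and level grids must be non-empty")
    silence = Waveform(np.zeros(int(round(dur * fs))), fs)
    spont = mean_rate(model.stage_rate(silence, stage))
    margin = max(0.2 * spont, 5.0)
    curves = []
    cf_est = None
    for level in sorted(levels):
        rates = np.array(
            [
                mean_rate(model.stage_rate(make_tone(f, dur, level, fs), stage))
                for f in freqs
            ]
        )
        curves.append(
            ResponseCurve(freqs, rates, np.zeros_like(rates), "RM-row", {"level_db": level})
        )
        if cf_est is None and np.any(rates > spont + margin):
            cf_est = float(freqs[int(np.argmax(rates))])
    return curves, cf_est


def classify_mtf(
    fms: np.ndarray,
    rates: np.ndarray,
    unmod_rate: float,
    enhance_ratio: float = 1.2,
    suppress_ratio: float = 0.8,
) -> MTFClassification:
    """Classify an MTF against its unmodulated reference.

    Band-enhanced: >= 2 contiguous modulation frequencies with rate >=
    ``enhance_ratio`` x unmodulated rate (BMF = argmax rate).  Band-suppressed:
    >= 2 contiguous with rate <= ``suppress_ratio`` x.  Flat: everything within
    the two ratios.  Otherwise "other".  Scale-invariant by construction.
    """
    fms = np.asarray(fms, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if unmod_rate > 0:
        hi = rates >= enhance_ratio * unmod_rate
        lo = rates <= suppress_ratio * unmod_rate
    else:  # a silent reference: any sustained response counts as enhancement
        hi = rates > 0
        lo = np.zeros_like(rates, dtype=bool)

    def two_contiguous(mask):
        return bool(np.any(mask[1:] & mask[:-1]))

    if two_contiguous(hi):
        return MTFClassification(
            "band-enhanced", float(fms[int(np.argmax(rates))]), unmod_rate
        )
    if two_contiguous(lo):
        return MTFClassification("band-suppressed", None, unmod_rate)
    if not np.any(hi) and not np.any(lo):
        return MTFClassification("flat", None, unmod_rate)
    return MTFClassification("other", None, unmod_rate)


def noise_mtf(
    model: TwoStageModel,
    fms=None,
    reps: int = 5,
    stage: str = "ic",
    seed: int | None = 0,
    dur: float = 1.0,
    fs: float = 100_000.0,
    band: tuple[float, float] = (100.0, 10_000.0),
    spectrum_level: float = 30.0,
    enhance_ratio: float = 1.2,
) -> tuple[ResponseCurve, MTFClassification]:
    """Noise MTF of a model stage, with shape classification.

    Each (modulation frequency, repetition) pair gets an independent noise
    token and fiber-noise draw; per-frequency rates are means over ``reps``
    repetitions and the spread is their standard deviation.  The unmodulated
    reference is measured the same way.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fms = mtf_frequencies() if fms is None else np.asarray(fms, dtype=float)
    conds = [0.0] + list(fms)  # leading 0 = unmodulated reference
    seeds = _spawn_seeds(seed, 2 * len(conds) * reps)
    means, spreads = [], []
    k = 0
    for fm in conds:
        vals = []
        for _ in range(reps):
            stim_seed, model_seed = seeds[k], seeds[k + 1]
            k += 2
            w = make_sam_noise(
                fm, 1.0, band, spectrum_level, dur, fs, seed=stim_seed
            )
            vals.append(mean_rate(model.stage_rate(w, stage, model_seed)))
        means.append(np.mean(vals))
        spreads.append(np.std(vals))
    unmod = float(means[0])
    curve = ResponseCurve(
        fms, means[1:], spreads[1:], "MTF", {"unmod_rate": unmod, "stage": stage}
    )
    return curve, classify_mtf(fms, means[1:], unmod, enhance_ratio)


def count_threshold_crossings(
    lam: RateFunction, threshold: float, refractory: float
) -> int:
    """Upward crossings of ``threshold`` with a refractory lockout."""
    if refractory <= 0:
        raise ValueError("refractory must be positive")
    above = lam.lam >= threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        idx = np.concatenate([[0], idx])
    lockout = int(round(refractory * lam.fs))
    count, last = 0, -lockout - 1
    for i in idx:
        if i - last > lockout:
            count += 1
            last = i
    return count


def click_mtf(
    model: TwoStageModel,
    rates=CLICK_RATES,
    count_threshold: float = 110.0,
    refractory: float = 1e-3,
    stage: str = "oct",
    dur: float = 1.0,
    level: float = 130.0,
    reps: int = 5,
    seed: int | None = 0,
    fs: float = 100_000.0,
) -> ResponseCurve:
    """Click MTF by threshold-crossing counts of the mean rate function.

    For each click rate, the stage response is averaged over ``reps``
    presentations and the upward crossings of ``count_threshold`` (with a
    refractory lockout) are counted; the curve reports counts per second.
    """
    rates = np.asarray(rates, dtype=float)
    seeds = _spawn_seeds(seed, len(rates) * reps)
    counts = []
    for j, r in enumerate(rates):
        w = make_click_train(r, level=level, dur=dur, fs=fs)
        lam = np.mean(
            [model.stage_rate(w, stage, seeds[j * reps + i]).lam for i in range(reps)],
            axis=0,
        )
        n = count_threshold_crossings(RateFunction(lam, fs), count_threshold, refractory)
        counts.append(n / dur)
    counts = np.array(counts)
    return ResponseCurve(
        rates,
        counts,
        np.zeros_like(counts),
        "clickMTF",
        {"count_threshold": count_threshold, "refractory_s": refractory, "dur_s": dur},
    )


def max_entrainment_rate(curve: ResponseCurve, tol: float = 0.05) -> float | None:
    """Highest click rate whose crossing count matches the click count.

    Entrainment at rate r means counts/s within ``tol`` of the presented
    click rate (clicks/s).  Returns None if no tested rate entrains.
    """
    if curve.kind != "clickMTF":
        raise ValueError("expected a clickMTF curve")
    dur = curve.meta.get("dur_s", 1.0)
    ok = [
        r
        for r, c in zip(curve.x, curve.rate)
        if np.floor(dur * r) > 0 and abs(c * dur - np.floor(dur * r)) <= tol * np.floor(dur * r)
    ]
    return float(max(ok)) if ok else None


def score_rvf_conditions(
    lam: RateFunction, events: EventLog, window: float = 0.015
) -> tuple[np.ndarray, np.ndarray]:
    """Per-velocity RVF rates from one rate function over a chirp sequence.

    Onset-aligned segments of each condition are averaged, the peak of the
    condition average located (earliest on ties), and a ``window``-long
    integration window centered at the peak (clipped to the segment) is
    converted to spikes/s.  Returns (velocities ascending, rates).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if len(events) == 0:
        raise ValueError("event log is empty")
    velocities = events.velocities()
    fs = lam.fs
    n_win = int(round(window * fs))
    rates = np.zeros(velocities.size)
    for j, v in enumerate(velocities):
        evs = events.for_velocity(v)
        seg_len = int(round((evs[0].offset - evs[0].onset + 0.030) * fs))
        segs = []
        for e in evs:
            i0 = int(round(e.onset * fs))
            if i0 + seg_len > lam.n:
                continue  # event window exceeds the record; skip
            segs.append(lam.lam[i0 : i0 + seg_len])
        avg = np.mean(segs, axis=0)
        peak = int(np.argmax(avg))
        a = max(0, min(peak - n_win // 2, seg_len - n_win))
        b = min(seg_len, a + n_win)
        rates[j] = np.sum(avg[a:b]) / fs / window
    return velocities, rates


def rvf(
    model: TwoStageModel,
    wave: Waveform,
    events: EventLog,
    window: float = 0.015,
    stage: str = "ic",
    reps: int = 5,
    seed: int | None = 0,
) -> ResponseCurve:
    """Rate-velocity function from a chirp-sequence presentation.

    For each repetition the whole sequence is run through the model once and
    scored per condition by :func:`score_rvf_conditions`.  Mean and standard
    deviation are taken over repetitions.
    """
    seeds = _spawn_seeds(seed, reps)
    velocities = events.velocities()
    per_rep = np.zeros((reps, velocities.size))
    for r in range(reps):
        lam = model.stage_rate(wave, stage, seeds[r])
        _, per_rep[r] = score_rvf_conditions(lam, events, window)
    return ResponseCurve(
        velocities,
        per_rep.mean(axis=0),
        per_rep.std(axis=0),
        "RVF",
        {"window_s": window, "stage": stage},
    )


def direction_bias(curve: ResponseCurve) -> tuple[np.ndarray, np.ndarray]:
    """Per-speed direction bias (R(+s) - R(-s)) / (R(+s) + R(-s)) in [-1, 1].

    Requires an RVF with paired +/- velocities; bias is 0 where both rates
    are 0.  Returns (speeds ascending, bias).
    """
    if curve.kind != "RVF":
        raise ValueError("expected an RVF curve")
    lookup = dict(zip(curve.x, curve.rate))
    speeds = np.array(sorted({abs(v) for v in curve.x}))
    bias = np.zeros_like(speeds)
    for i, s in enumerate(speeds):
        if s not in lookup or -s not in lookup:
            raise ValueError(f"velocity +/-{s} is not paired in the RVF")
        up, down = lookup[s], lookup[-s]
        bias[i] = 0.0 if up + down == 0 else (up - down) / (up + down)
    return speeds, bias
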