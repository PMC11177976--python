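"""Coincidence-detector algebra on instantaneous rate functions.

Model cells are treated as coincidence detectors receiving excitatory and/or
inhibitory inputs, each a nonhomogeneous-Poisson-process rate function λ(t).
The building block is the trailing window integral

    W(t) = ∫_{t-Δ}^{t} λ(t') dt'

interpreted as the probability that the input was active within the last Δ
seconds.  From it:

* an EE cell requiring all L inputs active fires at rate
  λ_EE(t) = Σ_l λ_l(t) · Π_{j≠l} W_j(t);
* a set Ω of inactive inputs contributes the survival product
  λ_I(t) = Π_j (1 - W_j(t));
* an exactly-l-of-N cell sums λ_EE(Ψ)·λ_I(Ω) over all active subsets Ψ;
* an EI cell multiplies its excitation by (1 - W_inh)^m for m identical
  inhibitory inputs.

The probabilistic reading requires W ≤ 1, which realistic auditory-nerve
rates violate over millisecond windows; W is therefore clamped to [0, 1] so
survival factors stay in [0, 1].  The resulting outputs are exact for small
rΔ and a graceful saturation beyond (the price being that the output is no
longer strictly an NHPP rate — see docs/methods.md).

Integration uses the rectangular rule at the native sample rate; delays are
whole-sample shifts with zero fill (nearest-sample rounding).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .frontend import RateFunction


def shift(x: RateFunction, delay: float) -> RateFunction:
    """Delay a rate function by ``delay`` seconds (zero-filled at the front)."""
    if delay < 0:
        raise ValueError("delay must be nonnegative")
    k = int(round(delay * x.fs))
    if k == 0:
        return x
    lam = np.concatenate([np.zeros(min(k, x.n)), x.lam[: max(x.n - k, 0)]])
    return RateFunction(lam, x.fs)


def window_integral(x: RateFunction, delta: float) -> np.ndarray:
    """Trailing-window integral ∫_{t-Δ}^{t} λ dt, clamped to [0, 1].

    For t < Δ the partial sum from 0 is returned.  The window length is
    rounded to whole samples and must be at least one sample period.
    """
    k = int(round(delta * x.fs))
    if k < 1:
        raise ValueError(
            f"delta {delta} s is below one sample period (1/fs = {1.0 / x.fs} s)"
        )
    c = np.cumsum(x.lam) / x.fs
    y = c.copy()
    y[k:] -= c[:-k]
    return np.clip(y, 0.0, 1.0)


def _check_ensemble(inputs: list[RateFunction]) -> None:
    if len({x.n for x in inputs}) > 1 or len({x.fs for x in inputs}) > 1:
        raise ValueError("all inputs must share sample rate and length")


def _windows(inputs: list[RateFunction], delta: float) -> list[np.ndarray]:
    """Window integrals with caching for repeated (identical-copy) arrays."""
    cache: dict[int, np.ndarray] = {}
    out = []
    for x in inputs:
        key = id(x.lam)
        if key not in cache:
            cache[key] = window_integral(x, delta)
        out.append(cache[key])
    return out


def _ee_from_windows(
    lams: list[np.ndarray], wins: list[np.ndarray]
) -> np.ndarray:
    n_in = len(lams)
    out = np.zeros_like(lams[0])
    for l in range(n_in):
        term = lams[l].copy()
        for j in range(n_in):
            if j != l:
                term *= wins[j]
        out += term
    return out


def ee_all_active(inputs: list[RateFunction], delta: float) -> RateFunction:
    """EE cell requiring activity on all inputs within a trailing window Δ.

    λ_EE(t) = Σ_l λ_l(t) · Π_{j≠l} ∫_{t-Δ}^{t} λ_j dt — the rate of the
    last-arriving input times the probability that every other input was
    recently active.
    """
    if len(inputs) < 2:
        raise ValueError("an EE cell needs at least 2 inputs")
    _check_ensemble(inputs)
    wins = _windows(inputs, delta)
    lam = _ee_from_windows([x.lam for x in inputs], wins)
    return RateFunction(lam, inputs[0].fs)


def inactive_term(omega: list[RateFunction], delta: float) -> np.ndarray:
    """Survival product Π_j (1 - W_j) of a set of inactive inputs.

    An empty set yields 1 everywhere (empty product).
    """
    if not omega:
        return np.ones(1)
    _check_ensemble(omega)
    out = np.ones_like(omega[0].lam)
    for w in _windows(omega, delta):
        out *= 1.0 - w
    return out


def ee_exactly_l(inputs: list[RateFunction], l: int, delta: float) -> RateFunction:
    """Cell responding when exactly ``l`` of N inputs are active.

    Sums, over every size-l active subset Ψ, the all-active EE rate of Ψ
    times the survival product of the complementary inactive set Ω.
    """
    n_in = len(inputs)
    if not 2 <= l <= n_in:
        raise ValueError(f"l must be in [2, {n_in}], got {l}")
    _check_ensemble(inputs)
    wins = _windows(inputs, delta)
    lams = [x.lam for x in inputs]
    out = np.zeros_like(lams[0])
    for active in combinations(range(n_in), l):
        aset = set(active)
        term = _ee_from_windows(
            [lams[i] for i in active], [wins[i] for i in active]
        )
        for j in range(n_in):
            if j not in aset:
                term = term * (1.0 - wins[j])
        out += term
    return RateFunction(out, inputs[0].fs)


def ei_inhibit(
    exc: RateFunction,
    inh: RateFunction,
    delta: float,
    m: int,
    delay: float = 0.0,
) -> RateFunction:
    """EI interaction: excitation times an m-fold inhibitory survival factor.

    out(t) = exc(t) · [1 - ∫_{t-Δ}^{t} inh(t' - delay) dt']^m, the effect of
    m identical independent inhibitory inputs.  m = 0 is the identity.
    """
    if m < 0:
        raise ValueError("m must be nonnegative")
    if exc.n != inh.n or exc.fs != inh.fs:
        raise ValueError("exc and inh must share sample rate and length")
    if m == 0:
        return exc
    w = window_integral(shift(inh, delay), delta)
    return RateFunction(exc.lam * (1.0 - w) ** m, exc.fs)
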