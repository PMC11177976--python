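"""IC stage: same-frequency inhibition/excitation plus octopus inhibition.

The model inferior-colliculus neuron receives one excitatory on-CF input
(λ_ANCF delayed by d_E, standing in for a brainstem relay), M_I delayed
same-frequency inhibitory copies of the same channel (the SFIE motif that
produces band-enhanced amplitude-modulation tuning), and M_Oct inhibitory
inputs from the chirp-selective octopus cell:

    λ_IC(t) = λ_ANCF(t - d_E)
              · [1 - ∫_{Δ_I}  λ_ANCF(t - d_I)]^{M_I}
              · [1 - ∫_{Δ_Oct} λ_Oct(t - d_Oct)]^{M_Oct},

half-wave rectified.  d_I > d_E so same-frequency inhibition trails
excitation; the octopus inhibition leads excitation (d_E > 0, d_Oct small),
so the IC cell inherits a chirp-direction preference opposite to that of its
octopus input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cd import shift, window_integral
from .frontend import RateFunction


@dataclass(frozen=True)
class ICParams:
    """IC-stage parameters.

    d_e : s — excitation delay (must be > 0 so octopus inhibition can lead).
    d_i, delta_i, m_i : same-frequency inhibition delay (> d_e), window Δ_I,
        and number of duplicated inhibitory inputs M_I.
    d_oct, delta_oct, m_oct : octopus-inhibition delay, window Δ_Oct, and
        input count M_Oct.
    """

    d_e: float
    d_i: float
    m_i: int
    m_oct: int
    delta_i: float = 1e-3
    delta_oct: float = 1e-3
    d_oct: float = 0.0

    def __post_init__(self):
        if self.d_e <= 0:
            raise ValueError("d_e must be positive")
        if self.d_i <= self.d_e:
            raise ValueError("d_i must exceed d_e (inhibition trails excitation)")
        if self.m_i < 0 or self.m_oct < 0:
            raise ValueError("m_i and m_oct must be nonnegative")
        if self.delta_i <= 0 or self.delta_oct <= 0:
            raise ValueError("integration windows must be positive")
        if self.d_oct < 0:
            raise ValueError("d_oct must be nonnegative")


def ic_response(
    lam_cf: RateFunction, lam_oct: RateFunction, p: ICParams
) -> RateFunction:
    """IC rate function λ_IC (see module docstring), half-wave rectified."""
    if lam_cf.n != lam_oct.n or lam_cf.fs != lam_oct.fs:
        raise ValueError("inputs must share sample rate and length")
    out = shift(lam_cf, p.d_e).lam.copy()
    if p.m_i > 0:
        w_i = window_integral(shift(lam_cf, p.d_i), p.delta_i)
        out *= (1.0 - w_i) ** p.m_i
    if p.m_oct > 0:
        w_o = window_integral(shift(lam_oct, p.d_oct), p.delta_oct)
        out *= (1.0 - w_o) ** p.m_oct
    return RateFunction(np.maximum(out, 0.0), lam_cf.fs)
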