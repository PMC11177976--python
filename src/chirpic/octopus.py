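"""Octopus-cell stage: sequence detection by coincidence + hyperpolarization.

The model octopus cell receives N = N_CF + 1 excitatory auditory-nerve
inputs: N_CF identical copies of the on-CF (suprathreshold) channel and one
off-CF (subthreshold) channel.  It fires when at least N - 1 of the N inputs
are active within the EE window Δ_EE, i.e. the sum of the exactly-N and
exactly-(N-1) coincidence rates.  Low-voltage-activated potassium (KL)
hyperpolarization is mimicked by two inhibitory survival factors — copies of
the excitatory inputs delayed by d_hyp, integrated over Δ_Hyp — so that an
input arriving shortly after any earlier activity is suppressed.  This makes
the cell a sequence detector: a sweep driving the suprathreshold CF input
before the subthreshold OCF input fires; the reverse order is vetoed by the
hyperpolarization that trails the OCF response.  Whether OCF sits above or
below CF therefore sets the preferred chirp direction.

Finally an ideal-onset threshold θ zeroes every sample below θ, confining
tone responses to the onset while preserving entrainment to transients.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cd import ee_exactly_l, inactive_term, shift
from .frontend import RateFunction


@dataclass(frozen=True)
class OctopusParams:
    """Octopus-stage parameters.

    cf, ocf : Hz — characteristic frequencies of the suprathreshold and
        subthreshold AN inputs (ocf != cf; its side sets direction preference).
    n_cf : number of identical CF copies (= L, the required active count - 0
        or 1); n_ocf is fixed at 1.
    d_cf, d_ocf : s — input alignment delays; at most one may be nonzero.
    delta_ee : s — EE coincidence window Δ_EE.
    delta_hyp, d_hyp : s — hyperpolarization window Δ_Hyp and delay.
    theta : spikes/s — ideal-onset threshold applied to the output.
    """

    cf: float
    ocf: float
    n_cf: int = 3
    n_ocf: int = 1
    d_cf: float = 0.0
    d_ocf: float = 0.0
    delta_ee: float = 1e-3
    delta_hyp: float = 2e-3
    d_hyp: float = 0.4e-3
    theta: float = 50.0

    def __post_init__(self):
        if self.cf <= 0 or self.ocf <= 0:
            raise ValueError("cf and ocf must be positive")
        if self.ocf == self.cf:
            raise ValueError("ocf must differ from cf")
        if self.n_cf < 2:
            raise ValueError("n_cf must be >= 2")
        if self.n_ocf != 1:
            raise ValueError("n_ocf is fixed at 1")
        if self.d_cf < 0 or self.d_ocf < 0 or self.d_hyp < 0:
            raise ValueError("delays must be nonnegative")
        if self.d_cf > 0 and self.d_ocf > 0:
            raise ValueError("at most one of d_cf, d_ocf may be nonzero")
        if self.delta_ee <= 0 or self.delta_hyp <= 0:
            raise ValueError("integration windows must be positive")
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")

    @property
    def upward(self) -> bool:
        """True if the cell prefers upward chirps (OCF above CF)."""
        return self.ocf > self.cf


def octopus_response(
    lam_cf: RateFunction, lam_ocf: RateFunction, p: OctopusParams
) -> RateFunction:
    """Octopus-cell rate function λ_Oct.

    1. Align inputs: shift λ_CF by d_cf and λ_OCF by d_ocf.
    2. EE coincidence over the N = n_cf + 1 inputs (n_cf identical CF copies
       plus the OCF input): sum of the exactly-N and exactly-(N-1) rates over
       window Δ_EE.
    3. Multiply by the two KL-hyperpolarization survival factors, one per
       input channel, each a copy of the aligned input further delayed by
       d_hyp and integrated over Δ_Hyp.
    4. Ideal-onset threshold: samples below θ are set to zero.
    """
    if lam_cf.n != lam_ocf.n or lam_cf.fs != lam_ocf.fs:
        raise ValueError("inputs must share sample rate and length")
    cf_in = shift(lam_cf, p.d_cf)
    ocf_in = shift(lam_ocf, p.d_ocf)
    inputs = [cf_in] * p.n_cf + [ocf_in]
    n_in = len(inputs)
    ee = ee_exactly_l(inputs, n_in, p.delta_ee).lam
    ee = ee + ee_exactly_l(inputs, n_in - 1, p.delta_ee).lam
    hyp = inactive_term(
        [shift(cf_in, p.d_hyp), shift(ocf_in, p.d_hyp)], p.delta_hyp
    )
    lam = ee * hyp
    lam[lam < p.theta] = 0.0
    return RateFunction(lam, lam_cf.fs)
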