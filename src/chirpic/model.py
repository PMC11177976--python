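"""Glue: run a waveform through front-end, octopus stage, and IC stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frontend import ANChannelSpec, RateFunction, an_rate
from .ic import ICParams, ic_response
from .octopus import OctopusParams, octopus_response

STAGES = ("an_cf", "an_ocf", "oct", "ic")


@dataclass(frozen=True)
class TwoStageModel:
    """A configured octopus(+IC) model bound to an AN backend.

    ``rates(w, seed)`` returns the rate function of every stage for one
    presentation of waveform ``w``.  ``seed=None`` gives the deterministic
    (noise-free) front-end; an integer seed draws independent fiber noise for
    the CF and OCF channels.
    """

    oct_params: OctopusParams
    ic_params: ICParams | None = None
    backend: str = "surrogate"
    n_fibers: int = 10
    spont: float = 60.0

    def rates(self, w, seed: int | None = None) -> dict[str, RateFunction]:
        if seed is None:
            seed_cf = seed_ocf = None
        else:
            children = np.random.SeedSequence(seed).spawn(2)
            seed_cf, seed_ocf = (int(c.generate_state(1)[0]) for c in children)
        lam_cf = an_rate(
            w,
            ANChannelSpec(self.oct_params.cf, self.n_fibers, 1, self.spont, seed_cf),
            self.backend,
        )
        lam_ocf = an_rate(
            w,
            ANChannelSpec(self.oct_params.ocf, self.n_fibers, 1, self.spont, seed_ocf),
            self.backend,
        )
        out = {"an_cf": lam_cf, "an_ocf": lam_ocf}
        out["oct"] = octopus_response(lam_cf, lam_ocf, self.oct_params)
        if self.ic_params is not None:
            out["ic"] = ic_response(lam_cf, out["oct"], self.ic_params)
        return out

    def stage_rate(self, w, stage: str, seed: int | None = None) -> RateFunction:
        if stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
        return self.rates(w, seed)[stage]
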