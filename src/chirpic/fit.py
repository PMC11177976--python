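"""Octopus-cell parameter optimization against step-template RVFs.

The free parameters are OCF (the subthreshold input's frequency) and a single
alignment delay applied to the higher-CF of the two AN inputs (d_cf if
ocf < cf, else d_ocf).  The loss is 1 - corr(RVF_model, RVF_template) where
the template is a step: rate 1 for the preferred direction's velocities and 0
for the opposite direction.  OCF bounds depend on the requested direction
(up: [cf, 3 cf]; down: [cf/3, cf]); the delay is bounded in [0, 2 ms].

Optimization is bound-constrained Nelder-Mead in a unit-normalized parameter
space, restarted from ``n_restarts`` random initial points; the best restart
wins.  Forward evaluations use the deterministic (noise-free) front-end so
the loss surface is reproducible; the chirp sequence is generated once per
fit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .characterize import ResponseCurve, score_rvf_conditions
from .frontend import ANChannelSpec, an_rate
from .octopus import OctopusParams, octopus_response
from .stimuli import DEFAULT_VELOCITIES, ChirpTrainSpec, make_chirp_sequence

DELAY_BOUNDS = (0.0, 2e-3)


def template_rvf(
    direction: str, velocities=DEFAULT_VELOCITIES
) -> ResponseCurve:
    """Step template: rate 1 for the preferred direction, 0 otherwise."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    x = np.array(sorted(velocities))
    rate = (x > 0).astype(float) if direction == "up" else (x < 0).astype(float)
    return ResponseCurve(x, rate, np.zeros_like(rate), "RVF", {"template": direction})


def correlation_loss(model_rates: np.ndarray, template_rates: np.ndarray) -> float:
    """1 - Pearson correlation; 2 (worst case) for a zero-variance RVF."""
    m = np.asarray(model_rates, dtype=float)
    t = np.asarray(template_rates, dtype=float)
    if np.std(m) == 0 or np.std(t) == 0:
        return 2.0
    return float(1.0 - np.corrcoef(m, t)[0, 1])


@dataclass(frozen=True)
class FitSpec:
    """Specification of one octopus-cell fit.

    ``n_cf=None`` picks the default copy count (4 below 2 kHz, else 3).
    ``chirp_reps`` is the number of presentations per velocity condition in
    the fitting battery; ``maxiter`` caps each restart's simplex iterations.
    """

    cf: float
    direction: str
    n_cf: int | None = None
    n_restarts: int = 3
    seed: int = 0
    chirp_reps: int = 10
    fs: float = 100_000.0
    maxiter: int = 40
    ocf_bounds: tuple[float, float] | None = None
    chirp_spec: ChirpTrainSpec | None = None
    oct_defaults: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.cf <= 0:
            raise ValueError("cf must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        bounds = self.ocf_bounds
        if bounds is None:
            bounds = (
                (self.cf, 3.0 * self.cf)
                if self.direction == "up"
                else (self.cf / 3.0, self.cf)
            )
            object.__setattr__(self, "ocf_bounds", bounds)
        if not bounds[0] < bounds[1]:
            raise ValueError("ocf bounds must satisfy low < high")

    @property
    def n_cf_resolved(self) -> int:
        return self.n_cf if self.n_cf is not None else (4 if self.cf < 2000 else 3)


@dataclass(frozen=True)
class FitResult:
    params: OctopusParams
    loss: float
    rvf_mod: ResponseCurve
    rvf_tem: ResponseCurve
    n_evals: int


def _build_params(spec: FitSpec, ocf: float, delay: float) -> OctopusParams:
    # the single delay goes to the higher-CF input
    if ocf < spec.cf:
        d_cf, d_ocf = delay, 0.0
    else:
        d_cf, d_ocf = 0.0, delay
    return OctopusParams(
        cf=spec.cf,
        ocf=ocf,
        n_cf=spec.n_cf_resolved,
        d_cf=d_cf,
        d_ocf=d_ocf,
        **spec.oct_defaults,
    )


def fit_octopus(spec: FitSpec, backend: str = "surrogate") -> FitResult:
    """Best-of-restarts fit of (OCF, delay) to the step-template RVF."""
    chirp_spec = spec.chirp_spec or ChirpTrainSpec(
        n_reps=spec.chirp_reps, seed=spec.seed
    )
    wave, events = make_chirp_sequence(chirp_spec, spec.fs)
    template = template_rvf(spec.direction, chirp_spec.velocities)
    lam_cf = an_rate(wave, ANChannelSpec(spec.cf), backend)
    ocf_cache: dict[float, object] = {}
    lo = np.array([spec.ocf_bounds[0], DELAY_BOUNDS[0]])
    hi = np.array([spec.ocf_bounds[1], DELAY_BOUNDS[1]])
    n_evals = 0

    def objective(u: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        ocf, delay = np.clip(lo + np.asarray(u) * (hi - lo), lo, hi)
        key = round(float(ocf), 1)
        if key not in ocf_cache:
            ocf_cache[key] = an_rate(wave, ANChannelSpec(key), backend)
        try:
            p = _build_params(spec, key if key != spec.cf else float(ocf), float(delay))
        except ValueError:  # ocf landed exactly on cf
            return 2.0
        lam_oct = octopus_response(lam_cf, ocf_cache[key], p)
        _, rates = score_rvf_conditions(lam_oct, events)
        return correlation_loss(rates, template.rate)

    rng = np.random.default_rng(spec.seed)
    best_u, best_loss = None, np.inf
    for _ in range(spec.n_restarts):
        u0 = rng.uniform(0.05, 0.95, size=2)
        res = optimize.minimize(
            objective,
            u0,
            method="Nelder-Mead",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            options={"maxiter": spec.maxiter, "xatol": 0.01, "fatol": 1e-3},
        )
        if res.fun < best_loss:
            best_loss, best_u = float(res.fun), res.x
    ocf, delay = np.clip(lo + best_u * (hi - lo), lo, hi)
    ocf = round(float(ocf), 1)
    params = _build_params(spec, ocf, float(delay))
    lam_oct = octopus_response(lam_cf, ocf_cache[ocf], params)
    velocities, rates = score_rvf_conditions(lam_oct, events)
    rvf_mod = ResponseCurve(
        velocities, rates, np.zeros_like(rates), "RVF", {"stage": "oct"}
    )
    return FitResult(params, best_loss, rvf_mod, template, n_evals)
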