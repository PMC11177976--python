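"""Presets, run configuration, and the end-to-end experiment driver.

Six example-neuron presets are shipped, named ``cf{1,4,8}k_{up,down}`` where
the direction is the *IC* cell's preferred chirp direction (its octopus-cell
input prefers the opposite direction).  Octopus-stage defaults not listed per
neuron (Δ_EE, Δ_Hyp, d_Hyp, θ, N_OCF) use the standard values baked into
:class:`~chirpic.octopus.OctopusParams`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .characterize import (
    classify_mtf,
    click_mtf,
    mtf_frequencies,
    noise_mtf,
    response_map,
    rm_frequencies,
    rvf,
)
from .ic import ICParams
from .model import TwoStageModel
from .octopus import OctopusParams
from .stimuli import ChirpTrainSpec, make_chirp_sequence

# (ocf_hz, d_cf_s, d_ocf_s, n_cf, m_oct, m_i, d_e_s, d_i_s, delta_oct_s, delta_i_s)
_PRESET_TABLE: dict[str, tuple] = {
    "cf1k_down": (2210.0, 0.0, 0.75e-3, 4, 12, 8, 1.0e-3, 3.5e-3, 1e-3, 1e-3),
    "cf1k_up": (900.0, 1.20e-3, 0.0, 4, 12, 16, 1.4e-3, 3.4e-3, 1e-3, 1e-3),
    "cf4k_down": (5330.0, 0.30e-3, 0.0, 3, 6, 16, 0.5e-3, 3.0e-3, 1e-3, 1e-3),
    "cf4k_up": (2240.0, 1.58e-3, 0.0, 3, 6, 8, 1.5e-3, 4.0e-3, 1e-3, 1e-3),
    "cf8k_down": (10690.0, 0.21e-3, 0.0, 3, 3, 8, 1.2e-3, 3.7e-3, 1e-3, 1e-3),
    "cf8k_up": (5510.0, 0.93e-3, 0.0, 3, 12, 8, 1.5e-3, 4.5e-3, 1e-3, 1e-3),
}
_PRESET_CF = {"cf1k": 1000.0, "cf4k": 4000.0, "cf8k": 8000.0}

PRESET_NAMES = tuple(sorted(_PRESET_TABLE))


def load_preset(name: str) -> tuple[OctopusParams, ICParams]:
    """Octopus and IC parameters of a named example neuron."""
    if name not in _PRESET_TABLE:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    ocf, d_cf, d_ocf, n_cf, m_oct, m_i, d_e, d_i, delta_oct, delta_i = _PRESET_TABLE[name]
    cf = _PRESET_CF[name.split("_")[0]]
    oct_p = OctopusParams(cf=cf, ocf=ocf, n_cf=n_cf, d_cf=d_cf, d_ocf=d_ocf)
    ic_p = ICParams(
        d_e=d_e, d_i=d_i, m_i=m_i, m_oct=m_oct, delta_i=delta_i, delta_oct=delta_oct
    )
    return oct_p, ic_p


def preset_model(name: str, backend: str = "surrogate") -> TwoStageModel:
    oct_p, ic_p = load_preset(name)
    return TwoStageModel(oct_p, ic_p, backend=backend)


BATTERIES = ("rm", "mtf", "click_mtf", "rvf")


@dataclass(frozen=True)
class RunConfig:
    """A reproducible experiment: preset + battery selection + seed."""

    preset: str
    outdir: str
    seed: int = 0
    backend: str = "surrogate"
    batteries: tuple[str, ...] = BATTERIES
    fs: float = 100_000.0
    reps: int = 5
    chirp_reps: int = 42
    rm_n_freqs: int = 30
    mtf_per_octave: int = 3
    mtf_dur: float = 1.0

    def __post_init__(self):
        if self.preset not in _PRESET_TABLE:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {', '.join(PRESET_NAMES)}"
            )
        bad = set(self.batteries) - set(BATTERIES)
        if bad:
            raise ValueError(f"unknown batteries {sorted(bad)}; available: {BATTERIES}")
        object.__setattr__(self, "batteries", tuple(self.batteries))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("run config must be a YAML mapping")
        return cls(**raw)


def _write_curve(curve, path: Path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format="%.8g")


def run_experiment(cfg: RunConfig) -> dict[str, str]:
    """Execute the selected batteries end to end and write results.

    Returns a mapping of output names to file paths.  Deterministic under a
    fixed seed: identical configs produce byte-identical files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = preset_model(cfg.preset, cfg.backend)
    outputs: dict[str, str] = {}

    def save(name, curve):
        path = outdir / f"{name}.csv"
        _write_curve(curve, path)
        outputs[name] = str(path)

    if "rm" in cfg.batteries:
        freqs = rm_frequencies(n=cfg.rm_n_freqs)
        for stage in ("oct", "ic"):
            curves, cf_est = response_map(model, freqs, stage=stage, fs=cfg.fs)
            for c in curves:
                save(f"rm_{stage}_{int(c.meta['level_db'])}db", c)
            outputs[f"cf_estimate_{stage}"] = cf_est
    if "mtf" in cfg.batteries:
        fms = mtf_frequencies(per_octave=cfg.mtf_per_octave)
        for stage in ("oct", "ic"):
            curve, cls = noise_mtf(
                model, fms, cfg.reps, stage, cfg.seed, cfg.mtf_dur, cfg.fs
            )
            save(f"mtf_{stage}", curve)
            cls_path = outdir / f"mtf_{stage}_classification.json"
            with open(cls_path, "w") as fh:
                json.dump(
                    {"label": cls.label, "bmf_hz": cls.bmf, "unmod_rate": cls.unmod_rate},
                    fh,
                    indent=2,
                )
            outputs[f"mtf_{stage}_classification"] = str(cls_path)
    if "click_mtf" in cfg.batteries:
        save("click_mtf_oct", click_mtf(model, reps=cfg.reps, seed=cfg.seed, fs=cfg.fs))
    if "rvf" in cfg.batteries:
        spec = ChirpTrainSpec(n_reps=cfg.chirp_reps, seed=cfg.seed)
        wave, events = make_chirp_sequence(spec, cfg.fs)
        for stage in ("oct", "ic"):
            save(f"rvf_{stage}", rvf(model, wave, events, stage=stage,
                                     reps=cfg.reps, seed=cfg.seed))

    meta = {
        "package_version": __version__,
        "preset": cfg.preset,
        "master_seed": cfg.seed,
        "backend": cfg.backend,
        "batteries": list(cfg.batteries),
        "fs_hz": cfg.fs,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    outputs["metadata"] = str(meta_path)
    return outputs
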