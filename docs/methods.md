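# Methods

## Model overview

The package implements a feed-forward, rate-based model of inferior-colliculus
(IC) chirp-velocity sensitivity and amplitude-modulation (AM) tuning. All
stages exchange *instantaneous discharge-rate functions* λ(t) (spikes/s) at a
common sample rate (default 100 kHz); no spike trains are drawn. Model cells
are coincidence detectors in the nonhomogeneous-Poisson-process (NHPP)
tradition: the probability that an input was active in the recent past is
represented by the trailing window integral W(t) = ∫_{t−Δ}^{t} λ(t′)dt′, and
excitatory coincidence and inhibitory veto are expressed as products of rates,
window integrals, and survival factors (1 − W).

### Coincidence algebra (`chirpic.cd`)

* `ee_all_active`: λ_EE(t) = Σ_l λ_l(t) Π_{j≠l} W_j(t) — the rate of the
  last-arriving input times the probability every other input fired within Δ.
* `ee_exactly_l`: Σ over all size-l active subsets Ψ of λ_EE(Ψ)·Π_{Ω}(1−W) —
  a cell requiring exactly l of N active inputs.
* `ei_inhibit`: exc·(1−W_inh)^m — m identical independent inhibitory inputs.

**Clamping.** The probabilistic reading requires W ≤ 1, but realistic AN
rates (hundreds of spikes/s) violate it over the millisecond windows this
model needs. W is clamped to [0, 1], which keeps survival factors in [0, 1]
and the algebra monotone and nonnegative. The price is that outputs are not
exact NHPP rates at these window lengths; the Monte-Carlo tests therefore
verify the algebra in its validity regime (rΔ = 0.02, where the first-order
window integral agrees with the true Poisson probability 1 − e^(−rΔ) to well
within simulation error), and the steady-state closed forms (2r²Δ;
3·2r(rΔ)(1−rΔ); exc·(1−rΔ)^M) are checked at rΔ = 0.1 to < 1%.

**Discretization.** Rectangular-rule integration at the native sample rate;
delays round to whole samples (zero-filled); for t < Δ the partial sum from 0
is used. Identical input "copies" share one array; the known statistical
dependence between copies is accepted, as is the dependence of the
hyperpolarization inputs on the excitation that drives them.

### Octopus-cell stage (`chirpic.octopus`)

N = N_CF + 1 excitatory inputs (N_CF identical on-CF copies + 1 off-CF), with
response = exactly-N + exactly-(N−1) coincidence over Δ_EE, multiplied by two
hyperpolarization survival factors (one per channel) built from the *aligned*
(d_CF/d_OCF-shifted) inputs further delayed by d_Hyp and integrated over
Δ_Hyp — hyperpolarization must track the excitation that causes it. The
printed equation leaves the delay placement implicit; this reading follows
the architecture's description of the inhibitory inputs as delayed copies of
the excitatory ones. Finally the ideal-onset threshold θ zeroes all samples
below θ.

Defaults (octopus): Δ_EE = 1 ms, Δ_Hyp = 2 ms, d_Hyp = 0.4 ms, θ = 50
spikes/s, N_OCF = 1, N_CF = 3 (4 for CFs below 2 kHz). At most one of
d_CF/d_OCF may be nonzero; zero is allowed for both because the optimizer's
delay bound includes 0.

### IC stage (`chirpic.ic`)

λ_IC(t) = λ_CF(t−d_E)·[1−∫_{Δ_I}λ_CF(t−d_I)]^{M_I}·[1−∫_{Δ_Oct}λ_Oct(t−d_Oct)]^{M_Oct},
half-wave rectified. d_E > 0 so the octopus inhibition (d_Oct = 0 by default)
leads excitation; d_I > d_E so same-frequency inhibition trails it. M_I and
M_Oct act as exponents (M identical independent inhibitory inputs multiply).
Δ_I = Δ_Oct = 1 ms for all presets.

The six presets pair each IC cell with an octopus input of the opposite
direction preference. Preset values (per-neuron OCF, delays, M_I, M_Oct,
d_E, d_I) are stored in `chirpic.config`; stage-level defaults above apply
where no per-neuron value exists. Two presets (`cf4k_down`, `cf8k_down`)
carry their alignment delay on the CF input even though the OCF input is the
higher-CF one; the stored table is authoritative for presets, while the
fitting module always delays the higher-CF input.

## Stimuli (`chirpic.stimuli`)

All stimuli are pressure waveforms in Pa; dB SPL is overall RMS re 20 µPa and
dB peSPL is the level of a sinusoid whose peak matches the transient's peak.
Calibration is applied to the final (ramped, modulated) waveform, so measured
levels equal requested levels exactly.

* **Tones**: 200 ms, 10-ms raised-cosine ramps; RM grid 250 Hz – 10 kHz
  (30 log-spaced points) × {10, 30, 50, 70} dB SPL.
* **SAM noise**: Gaussian noise brick-wall band-limited to 100 Hz – 10 kHz,
  spectrum level 30 dB SPL (overall ≈ 70 dB), multiplied by
  (1 + m·sin 2πf_m t) with m = 1, 50-ms ramps, 1 s duration, then rescaled to
  the carrier's nominal overall level so modulated and unmodulated stimuli
  are equal-level. Modulation grid: 3/octave over 2–500 Hz.
* **Clicks**: 0.1-ms rarefaction (negative) rectangular pulses, 130 dB peSPL,
  rates 2–900 Hz (the grid extends above 500 Hz to expose the entrainment
  limit).
* **Chirps**: one fundamental period of a Schroeder-phase complex is
  synthesized directly as a linear cosine sweep from F0 to 16 kHz, where F0
  solves (16000 − F0)·F0 = |v|·10⁶ (smaller root; F0 ≈ 25, 50, 100, 200,
  400, 600 Hz for the standard ±0.40…±9.24 kHz/ms velocities). Duration
  T = 1/F0, ramps 0.1·T, level 65 − 10·log₁₀(T/2.5 ms) dB SPL, which equates
  energy across velocities exactly. Sequences randomize 42 presentations per
  condition (test batteries use fewer) with uniform 40–60 ms gaps; an event
  log records onset/offset/velocity per presentation.

## Auditory-nerve surrogate (`chirpic.frontend`)

The cited phenomenological AN model (with efferent gain control) is out of
scope; the package ships a documented surrogate capturing the properties the
coincidence stages rely on, and a backend registry accepts external models
(waveform + fs + CF → rate + fs).

Chain: level-dependent 4th-order gammatone (complex one-pole cascade, unity
gain at CF; bandwidth = 1.019·ERB(CF)·(1 + max(0, L_pk − 60)/20) with L_pk
the stimulus peak level — high-level stimuli see broader, faster-ringing
filters, which keeps intense transients temporally compact) → half-wave
rectification → broken-stick compression (linear below a 1-mPa knee,
0.25-power above) → saturation s = c/(c + knee) → 6th-order Chebyshev-II
low-pass (40 dB stopband from 3.4 kHz; preserves envelope and low-CF fine
structure, removes fine structure at 4 kHz and above) → subtractive
adaptation rate = max(spont + drive·(s − 0.8·A), 0) with A = 0.75·LP₁ₘₛ(s) +
0.25·LP₆₀ₘₛ(s). Constants: spont 60 spikes/s, drive 2100 spikes/s.

Resulting behavior (all verified by tests): silence → spont; saturated
sustained tone rate ≈ 200–300 spikes/s with onset peak well above sustained
and post-onset dips below spont; ± 6 dB at saturation changes sustained rate
< 10%; click-onset latency decreases monotonically with CF (group delay);
thresholds near 0–10 dB SPL at CF. Fiber averaging: the "mean of 10 HSR
fibers" is realized as additive band-limited Gaussian noise (σ = 0.25·rate +
3 spikes/s per fiber) scaled by 1/√(n_fibers·n_reps); the deterministic rate
is exact in the noise-free limit.

**What the surrogate does not emulate.** Efferent gain control, power-law
(very slow) adaptation, refractoriness, and spontaneous-rate classes. Two
consequences matter for interpreting results: (1) worked examples tied to
the AN model's envelope dynamics shift — the 4-kHz example IC neuron's best
modulation frequency lands at ≈ 100 Hz as expected, but the 8-kHz example
peaks near 160 Hz instead of ≈ 40 Hz (it is still band-enhanced); the
octopus click-entrainment limit comes out at 500 Hz rather than 600 Hz
(within one tested click rate). (2) Run-to-run RVF spreads are small (< 4%
of rates) at both stages, so the physiological ordering "octopus error bars
smaller than IC error bars" is not resolvable under this noise model.
Response maps of the octopus/IC stages are non-monotonic with level near CF
(strong same-frequency inhibition), so the above-spontaneous CF rule is
exercised on the AN channel.

## Characterization (`chirpic.characterize`)

Rates are window integrals of λ over the stimulus duration divided by the
duration. Noise MTFs average 5 independent repetitions (fresh noise token and
fiber noise per repetition; spread = SD across repetitions). Classification:
band-enhanced iff ≥ 2 contiguous tested modulation frequencies have rate ≥
1.2 × the unmodulated rate (BMF = argmax); band-suppressed iff ≥ 2 contiguous
≤ 0.8×; flat if everything is within those ratios; otherwise "other". The
1.2/0.8 ratios are configurable; classification is invariant to uniform rate
scaling. Click MTFs count upward threshold crossings (110 spikes/s) of the
repetition-averaged rate function with a 1-ms refractory lockout, applied to
the θ-thresholded octopus output. RVFs average onset-aligned responses per
velocity condition, locate the condition-average peak (earliest on ties), and
integrate a 15-ms window centered there (clipped to the segment); direction
bias is (R₊ − R₋)/(R₊ + R₋) per speed, 0 when both rates are 0.

## Fitting (`chirpic.fit`)

Free parameters: OCF (bounds [CF, 3·CF] for upward targets, [CF/3, CF] for
downward) and one alignment delay ∈ [0, 2 ms] assigned to the higher-CF
input. Loss: 1 − Pearson correlation between the model octopus RVF and a
step template (1 for the preferred direction, 0 otherwise); a zero-variance
RVF scores the worst-case loss of 2. Optimization: Nelder-Mead in a
unit-normalized box, best of n_restarts ≥ 2 random starts (seeded), with the
CF channel's rate function cached across evaluations and OCF channels cached
at 0.1-Hz resolution. Forward evaluations use the deterministic front end so
the fit is exactly reproducible. The reference run (CF 4 kHz, seed 11,
2 restarts, 6 presentations/condition) reaches correlation ≈ 0.77 upward /
0.83 downward with OCF on the correct side of CF in both directions.

## Problem sizes

Test batteries use reduced but statistically stable sizes chosen for
stability of the condition averages: 8 chirp presentations per condition
(the full protocol's 42 is exercised in the sequence-construction checks and
available throughout), 2–5 model repetitions, 10–24 modulation frequencies.
The acceptance script uses the full modulation grid (24 points, 5
repetitions, 1-s stimuli) and the full click-rate grid at 1-s duration.

## Known limitations

* Outputs are not strict NHPP rates at the window lengths the mechanism
  needs (Δ_EE = 1 ms, Δ_Hyp = 2 ms); the package makes no claims about
  downstream statistical-decision-theory use.
* The surrogate front end is a stand-in: quantities tied to AN envelope
  dynamics (high-CF BMFs, exact entrainment limits) shift relative to runs
  with a full AN model; plug one in through the backend registry for those.
* Band-suppressed IC types and binaural input are out of scope.
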