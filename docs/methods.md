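# Methods

`phrenosweep` simulates and analyses automated phrenic-nerve-stimulation
(PNS) pattern evaluation: which combinations of pulse width, pulse
frequency, polarity scheme and envelope ramp produce the largest
body-weight-scaled tidal volume (`V_T,bw`, mL/kg) in a deeply sedated,
mechanically ventilated subject.  Because no animal data are deposited,
the experiment runs against a *virtual pig* — a synthetic respiratory
model calibrated so that the published structural findings (baseline
calibration window, frequency/width saturation, polarity asymmetries,
correlation bands) emerge from the simulation rather than being asserted.

## Stimulation model

A stimulated breath is one *burst*: a pulse train at rate `f_p` (Hz) whose
amplitude follows a trapezoidal envelope from `v_start` to `v_end` over
`T_slope`, then flat until `T_burst`.  Pulses are `UNI` (one polarity),
`ALT` (polarity alternating between pulses) or `BIP` (two equal,
charge-balanced phases of `T_pw/2` inside each pulse, no interphase gap).
The burst contains every pulse whose onset lies strictly below `T_burst`.
Hardware limits are modelled only as behaviour: a 20 V amplitude ceiling
and a series resistance (default 1667 Ω, i.e. 12.0 mA at 20 V).

Whether `T_pw` denotes the total biphasic width (split into two phases)
or the per-phase width is genuinely ambiguous in stimulator conventions;
the package defaults to the total-width reading (`bip_total_width=True`)
and exposes the switch in the configuration.

## Virtual-pig model

**Lung mechanics.** A single linear compartment,
`R_aw * dV/dt + V/C = P_drive(t)`, with compliance `C = 30 mL/cmH2O` and
airway resistance `R_aw = 20 cmH2O·s/L` (time constant τ = 0.6 s); body
weight 49 kg (animal-I preset) or 41 kg (animal-II).  Mandatory breaths
apply `p_insp − p_PEEP` for the inspiration time; stimulated breaths are
driven by diaphragm pressure

    P_mus(t) = P_max · recruit(env(t), T_pw,eff) · gain(f_eff)

with `P_max = 11.5 cmH2O`, followed by passive expiration.  Integration
is fixed-step RK4 at 1 ms (configurable; a step above τ raises an error
instead of returning garbage), decimated to the 10 ms acquisition grid.

**Excitability.** The Lapicque strength-duration law
`v_exc = v_rh (1 + T_ch / T_pw,eff)` with rheobase `v_rh = 2.6 V` and
chronaxie `T_ch = 0.13 ms`; graded recruitment is a logistic in
`v − v_exc` with slope 0.5 V (0.5 exactly at threshold, < 0.05 at 0 V).

**Force-frequency.** A Hill saturation `f^n / (f^n + f50^n)` with
`f50 = 25 Hz`, `n = 2.5`, so the gain reaches ≈ 0.95 at 80 Hz — the
published onset of the biphasic frequency plateau.

**Polarity effects.** BIP acts with the halved phase width
(`T_pw,eff = T_pw/2`); ALT drives each electrode site on alternate pulses
(`f_eff = f_p/2`) and is subject to an electrode-polarisation threshold
shift that evolves as a reflecting random walk per ALT burst (step sd
`0.5 V × alt_instability`; 0 = consistent animal I, 2 = inconsistent
animal II).  This reproduces the observed asymmetries: BIP at
`T_pw = 0.05 ms` is ineffective (half-width below threshold at 10 V)
while ALT at 0.05 ms still recruits; ALT saturates at roughly twice the
biphasic plateau frequency; the unstable-ALT animal's ALT medians
collapse below its BIP medians.

**Noise.** One multiplicative Gaussian factor on `P_max` per breath
(sd 5%) and additive flow noise per 10 ms sample (sd 0.01 L/s); all
randomness derives from a single root seed via counter-based
`SeedSequence` splitting, one child per breath, so reruns are
byte-identical.

### Calibration rationale

The study animals' physiological constants are unpublished, so `C`,
`R_aw`, `P_max` and the excitability values are calibration choices, set
once, analytically, against the published windows:

* `v_rh = 2.6 V`, `T_ch = 0.13 ms` place the biphasic thresholds so that
  `v_exc(0.025 ms) ≈ 16 V` (BIP/0.05 ms unexcitable at 10 V),
  `v_exc(0.075 ms) ≈ 7.1 V` (BIP/0.15 ms near-fully recruited, width
  plateau at 0.15 ms) and `v_exc(0.05 ms) ≈ 9.4 V` (ALT/0.05 ms partially
  effective).  A larger chronaxie (e.g. 0.2 ms) would push
  `v_exc(0.075 ms)` to ≈ 15 V and make BIP at 0.15 ms unexcitable,
  contradicting the published response surface.
* `C·P_max` sets the baseline tidal volume.  The first-order lag factor
  `1 − exp(−T_burst/τ) ≈ 0.84` attenuates the quasi-static volume
  `C·P_mus`, so `P_max = 11.5 cmH2O` lands the baseline pattern (4 ms,
  200 Hz, ALT, 1.0 s ramp, 10 V) at ≈ 5.7 mL/kg, mid-way through the
  published 5–6.5 mL/kg calibration window.

### What the generator does and does not emulate

It emulates: 10 ms flow/pressure/phase traces, saturation in both
frequency and width, ALT/BIP asymmetry, breath-to-breath noise, baseline
drift hooks (`drift_rate`), inter-animal variability (log-normal
parameter sampling with range clamps, plus the two named presets).  It
does **not** emulate gas exchange, nonlinear compliance, chest-wall
partitioning, diaphragm fatigue, electrode repositioning, or the single
anomalous high-volume ALT pattern reported at 142 Hz / 1.0 ms (no stated
mechanism, deliberately not reproduced).  Passing tests therefore show
that the *pipeline* recovers the structure a plausible physiology
produces — not that these parameter values describe any real animal.

## Experiment pipeline

**Scheduling.** One cycle of `60/f_mv` seconds is laid out as mandatory
inspiration, mandatory expiration, burst, stimulated expiration, with
user-set expiration minimums.  The burst is anchored from the cycle end
(the stimulated expiration keeps exactly its minimum; slack goes to the
mandatory expiration) — the conservative reading of the published timing
diagram, which draws the order but not the anchoring.  Intervals are
half-open; infeasible component sums raise before anything runs.

**Sweep.** The canonical grid uses frequencies
{10, 20, 40, 60, 80, 100, 120, 142, 200, 208} Hz and widths
{0.05, 0.1, 0.15, 0.2, 0.3, 0.5, 1.0} ms — reverse-engineered: the
publication prints only ranges (10–208 Hz, 0.05–1.0 ms) and the counts
70/71 per subgroup, and these lists contain every grid value it quotes.
Order is subgroup-major, widths outer, frequencies inner.  The baseline
pattern (4 ms, 200 Hz, 1.0 s ramp; ALT for animal I, BIP for animal II)
is a member of its matching subgroup — the only reading consistent with
71 vs 70 — and is additionally executed before the first pattern, after
every ten patterns, and once more after a final partial block, so drift
brackets every pattern.  Five breaths per pattern;
`V_T,bw = max_T ∫ flow/m_body` by trapezoid on the 10 ms grid, never
negative.

**Strength-duration stage.** Threshold search by bisection on `v_end` in
[0, 20 V] to 0.05 V, flat burst (`T_slope = 0`, 1.10 s) at 100 Hz,
noise-free; a breath is *excited* when peak burst-window flow exceeds
0.05 L/s (strict).  20 V failing is a valid not-excitable outcome.  The
Lapicque fit is linear least squares of `v` against `1/T_pw` — exact on
noiseless points and closed-form reproducible.  Note the flow criterion
fires at ≈ 9% recruitment, so measured thresholds sit a fixed
`≈ 2.3 × (recruitment slope)` below the 50%-recruitment voltage; with the
default 0.5 V slope that is ≈ 1.1 V.  The fit's intercept absorbs the
offset, which is why parameter-recovery checks use a sharp-recruitment
animal.

**Analysis.** Quartiles by linear interpolation of order statistics (the
common default; the publication states no convention), whiskers at the
extrema of non-outliers, outliers beyond 1.5 IQR.  Pearson correlations
are two-tailed with the t-transform on n−2 df; p-values are reported raw
(the study applies no multiple-testing correction).  Plateau onset is the
smallest grid value whose per-pattern mean reaches 95% of the axis
maximum ("approx." in the source; 95% is the tunable default), flagged
when first reached only at the last grid value; the rule is invariant to
rescaling the volume axis.  Because the response is monotone saturating
by construction, the rule is applied to the isotonic (non-decreasing
least-squares) fit of the means: thresholding on the raw maximum of noisy
per-pattern means is upward biased — a single high draw at the axis end
can push the detected onset past the entire plateau — while the isotonic
fit is the identity on monotone data, so noise-free detection is
unchanged.  Response surfaces are exported as bilinear interpolation
tables rather than rendered 3-D plots.

## Numerical and robustness notes

* Noise-free, the biphasic plateau onsets are exactly 80 Hz (frequency
  axis at 0.3 ms) and 0.15 ms (width axis at 80 Hz).  With the default
  breath noise, a five-breath pattern mean carries ≈ 2% standard error
  while the 80 Hz gain sits ≈ 0.3% above the 95% detection threshold, so
  the detected onset can move one grid step (typically to 100 Hz or
  0.2 ms) depending on the seed — occasionally further on the width axis,
  where the margin is thinnest.  This is inherent to placing the
  half-saturation curve's 95% point on a grid value.
* The ALT frequency plateau falls structurally at 142 Hz on this grid:
  with `f_eff = f_p/2`, the ALT gain at 120 Hz is 92% of its 208 Hz value
  (below the 95% rule) and crosses at 142 Hz — one grid step above the
  80–120 Hz band quoted for the animals.  A parameterisation putting ALT
  at ≤ 120 Hz *and* BIP at 80 Hz simultaneously has sub-1% margins under
  the halved-rate mechanism and was rejected as non-robust.
* Problem sizes: the full sweep is 281 patterns + 30 baselines × 5
  breaths = 1 555 breaths (≈ 4 s on one core); tests and the acceptance
  script run it once and reuse the result.

## Known limitations

Single-compartment linearity means volume conservation holds exactly
only once passive expiration completes; the scheduler's stimulated
expiration window (≈ 0.5 s against τ = 0.6 s) truncates emptying, and
each breath is simulated independently from functional residual capacity
rather than chaining residual volumes.  The tidal-volume statistic is
insensitive to this truncation (its maximum is reached at end-burst).
Voltage-controlled stimulation only; electrode anatomy, current-controlled
pulses and the stimulator electronics are out of scope.
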