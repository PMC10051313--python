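# Methods

## Scope and model

`bnctmon` implements the computational chain of an on-line BNCT
irradiation monitor: raw fission-chamber counting → dead-time
correction → normalisation by a foil-calibrated reference rate →
boron-weighted dose accumulation → session bookkeeping. Doses arrive
pre-weighted (cGy-w) from a treatment-planning system; the package does
no voxel dosimetry, RBE/CBE modelling, or neutron transport, and the
GUI/network layers of a control-room deployment are out of scope.

### Dead-time correction

The distortion is modelled as `CR_meas = A·CR + B·CR²` with `A > 0`
dimensionless and `B` in (counts/s)⁻¹; `B < 0` represents counting
losses. The inversion uses the physical root of the quadratic,
evaluated in the conjugate form `2·CR_meas / (A + √(A² + 4·B·CR_meas))`.
This is algebraically identical to `(−A + √(A² + 4·B·CR_meas)) / (2B)`
but avoids catastrophic cancellation as `|B| → 0` and yields the
`B = 0` limit `CR_meas/A` without a special case; round-trip accuracy is
better than 1e−9 relative across the physical branch and continuity at
`B = ±1e−15` is within 1e−6. A measured rate with negative discriminant
is reported as saturation (outside the invertible range); a true rate
driven past the parabola's zero crossing (`−A/B` for `B < 0`) is a range
error that names the admissible maximum. `(A, B)` estimation from a
(true, measured) sweep is an exact linear least-squares solve on the
design `[CR, CR²]` — the model is linear in its coefficients — with
residual-based standard errors for uncertainty-aware recovery checks.

Only the non-paralyzable quadratic form is supported; paralyzable
models and pulse-pileup electronics are not.

### Foil calibration

`CR_ref = (RR_ref/A_foil)·Σ_t CR_t (1−e^{−λ}) e^{−λ(T−t)}` is evaluated
with a one-second tick (the acquisition cadence), so `λ` must be
supplied per second. The weight `1 − e^{−λ}` is computed with `expm1`
so slow decays (λ ~ 1e−5 s⁻¹) lose no precision; the vectorized sum
agrees with a term-by-term `fsum` oracle to 1e−12 relative up to
T = 10⁴. `A_foil` is taken as the decay-referenced end-of-irradiation
activity as supplied; any decay-to-counting-time correction is the
caller's. When both Au and Cu foils are given, their per-foil reference
rates are combined as an unweighted mean — the simplest defensible rule
absent a stated combination; a facility with known per-foil
uncertainties should weight accordingly and pass a single value.

### Dose accumulation

Tick length is 1 s. Registration begins on the first tick whose *raw*
control-channel counts exceed 100 in the tick and is latched: dips below
threshold (and the scram tail) keep accumulating until the operator
stops the session. Raw counts are used because the threshold guards
onset at low rates, where the correction is the identity to well below
the counting noise.

Dose is computed per channel but one control channel (default "A",
i.e. the first chamber) is authoritative; the others are cross-checks.
The cross-check warns when another channel's normalised rate deviates
from the control's by more than 5 % (configurable), but only on ticks
with enough counts that three Poisson standard deviations fit inside
the band (N > 9/tol², i.e. 3600 counts at 5 %) — below that the
comparison is statistically meaningless and would flood the log during
ramp-up and run-down.

Concentration handling: the timeline of measured boron concentrations
is piecewise-constant with last-value-carried-forward (draws are sparse
— typically 1 h, 2 h, post), and the planned concentration applies
before the first draw. A new measurement re-scales the boron component
of *all* registered ticks via the stored per-tick counting-rate ratios,
producing the corrected prescription dose; the as-registered total is
retained unchanged, so the monitor can always display both. This
recomputation is exact, idempotent, and linear in the boron component.

The shutdown signal fires (and latches) when the corrected dose reaches
`target × rundown_pct/100` with `rundown_pct` default 100; the
configurable fraction lets an operator schedule the reactor run-down
early enough that the tail completes the prescription. The remaining
time estimate is `remaining dose / current total dose rate`, undefined
(None) while dose remains but the beam is off.

### Session model

Fields follow the strict lattice open → irradiation → final; a field
can only be finalized after at least one registered dose tick, and only
one field irradiates at a time. Plan selection operates per field
geometry over the offered planned-concentration variants, choosing the
variant nearest the measured blood concentration and breaking ties
toward the higher concentration (a 35 ppm measurement against 30/40 ppm
variants selects 40 ppm). Selection marks the chosen variants; it does
not itself start irradiation — the single-irradiating-field rule is
enforced at `start_field`. Triplicate ICP-OES readings are averaged
arithmetically; the mean is what feeds the engine. Persistence is a
flat directory of JSON and CSV; floats are written with shortest-repr
and read back with round-trip parsing, so save/load/save is
byte-identical.

## Synthetic telemetry

The simulator emulates the operational shape of a reactor BNCT session:
linear ramp to operating power (defaults 1.7 MW over 240 s), plateau,
and exponential scram (τ = 20 s) triggered by the engine's shutdown
signal; beam counting is zero below 20 kW, then Poisson about
`gain × power/1.2` per channel and distorted by that channel's
dead-time model (default A = 1, B = −1e−7 — a plausible few-percent
loss at 10⁵ counts/s; real coefficients are facility calibration data).
Channel gains default to 10⁵ counts/s at 1.2 MW; absolute reference
rates are facility-specific, so every numeric test sets them
explicitly. The ramp is modelled linear and the onset as a hard cutoff;
real start-ups are operator-shaped and the beam grows gradually — the
simulator reproduces the timescales and the statistics, not the control
history. Passing tests therefore demonstrate the correctness of the
monitoring arithmetic and workflow under realistic counting noise, not
the behaviour of any particular reactor.

Fixed-duration mode (no scram insertion) supports constant-conditions
replays, such as the recorded mouse experiment: 1750 one-second ticks at
counting ratio 1.28/1.2 with boron/background rates 0.1417/0.18 cGy-w/s
accumulate 600.51 cGy-w against the 600 cGy-w target, matching the
recorded 600.21 cGy within the rounding of the 3–4 significant-figure
inputs. The a-priori "30 min at 1.2 MW" estimate for that run is not
reproducible from the printed rates (0.3217 cGy-w/s × 30 min ≠ 600
cGy-w) and is treated as operator rounding, not a checked quantity.

## Numerical and design choices

- All accumulator state is double precision; sums are sequential (a
  session is ~10³–10⁴ ticks, far below any compensated-summation need).
- Registration threshold comparisons are strict (`> 100`), run-down and
  band checks inclusive (`≥`, closed interval), matching the natural
  reading of "more than" vs "reaches".
- Out-of-order or duplicate telemetry timestamps are stream errors;
  paused ticks are logged but not accumulated, and elapsed time counts
  only registered ticks.
- The dose engine accepts a target strictly positive; degenerate
  "complete immediately" cases are modelled with a target below one
  tick's increment.
- Problem sizes in the test suite (10³ property triples, T ≤ 10⁴ foil
  series, ~2×10³-tick scenarios) keep the whole suite under a few
  seconds while exercising every code path at realistic rates.

## Known limitations

- Non-paralyzable quadratic dead time only; no pile-up or gain-drift
  modelling.
- The Au/Cu combination rule (unweighted mean) is a convention, not a
  measurement-driven weighting.
- The gamma channel is recorded and simulated but carries no dose
  contribution (doses are pre-weighted by the planning system).
- Single-process file store; no concurrency, authentication, or
  networked sharing.
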