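# Methods

## Model

The runner is reduced to two point masses on one vertical, up-positive
axis. The lower mass `m2` (support leg) rests on a linear spring `k2` in
parallel with a viscous damper `c`; the upper mass `m1` (everything
else) is connected to it by a second linear spring `k1`. Positions are
displacements from the unloaded spring lengths and gravity
g = −9.81 m s⁻² acts on both masses; the model covers stance only
(touchdown to take-off), has no flight phase and no active elements.

The package works with the scaled parameterisation
(p1, p2, v1, v2, ω₁², ω₂², λ, ζ) plus total mass M, where λ = m1/m2,
ω₁² = k1/m1 and ω₂² = k2/m2 are the squared natural frequencies (s⁻²),
and ζ = c/(2√(k2·m2)) is the damping ratio of the lower element.
Conversion to and from physical masses/stiffnesses is exact and tested
to round-trip at 1e-12 relative.

Two conventions deserve emphasis because they are easy to get wrong in
this model family:

* the damping acceleration on the lower mass is `2ζω₂v2` — first power
  of ω₂. This is the only dimensionally consistent form and the one
  under which the model GRF equals the lower-element force `k2·p2+c·v2`.
* the model GRF is `−(k2 p2 + c v2)`, the sign chosen so that spring
  compression (p2 < 0) and downward lower-mass velocity (v2 < 0) give a
  positive upward force. With this sign the Newton identity
  `GRF = m1(a1−g) + m2(a2−g)` holds exactly along every trajectory and
  is enforced in the test suite at 1e-9 relative.

ω₁² = 0 (and k1 = 0) is deliberately admitted: it decouples the upper
mass into free fall, which provides the closed-form limits used to
validate the integrator. The configured g may also be set to 0 for
conservation checks; it must be non-positive.

## Integration

Classic fixed-step 4th-order Runge-Kutta on the four first-order state
equations. The default step is the force-platform sampling interval
(dt = 1/3000 s), so the model grid and the measured GRF grid coincide
and no resampling is needed on the force side. Fixed-step RK4 was
preferred over adaptive stepping for determinism and because the
stiffest mode (ω₂ ≤ √8000 ≈ 90 rad s⁻¹) gives ω·dt ≈ 0.03, far inside
the stability region. A state that becomes non-finite or implausibly
large (|p| > 1e6) aborts integration; the public API raises a
diverged-simulation error carrying the last valid time, while the
fitting objectives convert divergence into a large finite penalty
(1e6 in objective units) so a line search can back away from an
unstable parameter region. Verified properties: free-fall limit exact to
machine precision, underdamped-oscillator limit below 1e-6 m at
dt = 1e-4, observed order-4 error convergence (ratio 12–20 on step
halving), and mechanical-energy drift below 1e-6 relative over 0.5 s
with ζ = 0 and g = 0.

## Signals

GRF is handled in newtons at 3,000 Hz, trunk accelerometry as resultant
proper acceleration in g at 100 Hz (a static stance reads 1 g; free
fall reads 0 g). The model's accelerometer-equivalent channel is
(a1 − g)/9.81, so gravity "correction" is a no-op in this convention; a
subtract-1g alternative is exposed for pipelines that prefer
zero-referenced dynamic acceleration.

Filtering is zero-lag (forward-backward) Butterworth with the requested
order split across the two passes — the biomechanics convention for a
"4th-order recursive" filter — with reflective edge padding and no
cut-off correction factor. The dual-pass attenuation at the cut-off is
−6.02 dB. Stance is delimited by a 20 N threshold: touchdown is the
first supra-threshold sample and take-off the end of the contiguous
supra-threshold run containing the force maximum, which makes the rule
insensitive to isolated noise crossings. Indexing is 0-based and
inclusive on both ends.

Comparisons are made on the grid of the measured signal: model output is
interpolated linearly onto the 100 Hz accelerometer grid for the
accelerometry objective and onto the 3,000 Hz platform grid (an
identity when dt = 1/3000) for the force objective. The accelerometer
target's start offset relative to platform-defined touchdown (up to one
100 Hz sample) is carried explicitly. Fits are windowed to stance and
both channels low-passed at 20 Hz first; on stance windows too short to
support the filter pad the filter order degrades gracefully (4 → 2 →
unfiltered) rather than failing.

## Fitting

Both routes minimise a waveform RMSE over the eight parameters: the
accelerometry route fits the upper-mass proper acceleration to the
trunk signal (objective in g), the force route fits the model GRF to
the body-mass normalised measured GRF (objective in N/kg).

The optimiser is projected gradient descent in dimensionless
coordinates (each parameter divided by a characteristic scale: 0.05 m
for positions, 1 m s⁻¹ for velocities, 500 and 2,000 s⁻² for ω₁² and
ω₂², 1 for λ, 0.3 for ζ), with:

* central-difference gradients (relative step 1e-5 per scaled
  coordinate; one-sided fallback when a probe lands in a diverged
  region; fixed parameters get gradient 0);
* a Barzilai-Borwein initial step, safeguarded to [1e-10, 1e3];
* a backtracking line search (halve until decrease, up to 40 times)
  followed by a greedy expansion (double while the objective keeps
  dropping), with projection onto the bounds at every probe;
* convergence when the relative decrease stays below `tol` (default
  1e-6) for five successive accepted steps, or at `max_iters`.

Bounds span the physically plausible running regime: p1, p2 ∈ [−0.10,
0.05] m; v1, v2 ∈ [−4, 1] m s⁻¹; ω₁² ∈ [50, 2000] s⁻²; ω₂² ∈ [500,
8000] s⁻²; λ ∈ [0.3, 10]; ζ ∈ [0, 1.2]. Restarts are drawn uniformly
inside the bounds from the seed; the best endpoint wins (ties to the
lowest restart index) and **all** endpoints are kept in the result,
because the objective is non-identifiable: materially different
parameter vectors reach near-identical objectives, which is central to
why the accelerometry route fails. A fixed-parameter mask (used by the
sensitivity experiment) pins chosen parameters to given values in every
start and every step.

Two optimiser regimes are used. Batch (cohort) runs use 4 restarts and
150 iterations per restart — enough for force-route replication errors
far below the accelerometry-route prediction errors they are compared
against. Parameter-recovery checks use 8 restarts and 1,500 iterations,
since plain gradient descent converges slowly on this ill-conditioned
objective; a diagonally preconditioned variant was tried and rejected
(the objective's strong cross-couplings made it worse).

## Synthetic cohort

No recorded trials ship with the package; a generator emulates the
study-grade instrumentation so every stage is testable.

Ground truth is drawn per trial from triangular distributions whose
modes and supports are the force-route parameter medians and
interquartile ranges reported for overground running at 2, 3, 4 and
5 m s⁻¹ (nearest nominal speed): lower-element stiffness ω₂² and
touchdown-velocity magnitude |v1| rise with speed; p2 ≈ 0,
v2 ≈ −0.02 m s⁻¹ and ζ ≈ 0.36 define the physical regime. Where the
printed interquartile range is degenerate the parameter is held at its
median. Stance duration is the truth model's own take-off (first GRF
zero crossing after the force maximum), so model and "measured" contact
time agree by construction in the noiseless limit; draws whose GRF
never returns to zero (strongly damped combinations) are redrawn.

The instrument model, all settings exposed on `DeviceModel`:

* force platform: 3,000 Hz, additive white noise (default sd 5 N —
  typical in-ground platform noise floor);
* accelerometer: the model's upper-mass proper acceleration plus a
  damped sinusoidal impact-shock artifact A·e^(−t/τ)·sin(2πft) with
  f = 15 Hz, τ = 40 ms, and A scaling linearly from 3 g at 2 m s⁻¹ to
  6 g at 5 m s⁻¹ — the foot-strike shock transmitted up the spine,
  which a rigid two-mass model cannot produce and which makes the first
  accelerometer peak dominate the second at every speed, as in measured
  trunk signals; additive white noise (default sd 0.03 g); a 50 Hz
  second-order single-pass low-pass standing in for the device's
  (undisclosed) internal filter; 100 Hz sampling; clipping at ±13 g.
  Setting the amplitudes to 0 disables the artifact; `device_lowpass =
  None` disables the filter; `DeviceModel.ideal()` is the fully
  pass-through preset used by self-consistency tests.

The default cohort is 20 subjects (mass 76 ± 11 kg, truncated at
45–120 kg), 4 trials at each of 4 nominal speeds jittered ±5%, i.e. 80
trials per speed and 320 in total, all randomness derived from one
seed.

What the generator does **not** emulate: multi-segment (wobbling-mass)
dynamics, swing-leg and arm accelerations, tri-axial sensor geometry
and orientation drift, footwear effects, or speed measurement error
beyond the ±5% jitter. Consequently, passing tests show that the
pipeline behaves as designed on data that satisfy the model's own
assumptions plus instrument artifacts — they do not certify accuracy on
real runners, where the upper-mass-equals-trunk assumption itself is
the dominant error source.

## Cohort pipeline and experiments

Per trial, three errors are reported: the accelerometer-fit RMSE (g),
the RMSE of the GRF predicted from the accelerometry-route parameters
(N/kg), and the RMSE of the GRF replicated by the force route (N/kg).
The prediction is simulated over the measured stance window; any model
contact-time mismatch is absorbed into the RMSE, not truncated away.
Summaries are medians with 25th–75th percentiles (linear interpolation
between order statistics), per speed and overall. Extreme trials are
flagged — never deleted — by a q75 + 3·IQR rule per speed group and
metric, a reproducible stand-in for visual outlier screening; flagged
rows are excluded from summaries only on request.

The fixed-parameter experiment re-runs the accelerometry route with
p2 = 0.00 m, v2 = −0.02 m s⁻¹ and ζ = 0.36 pinned in the five
combinations (none; p2; v2; p2+v2; p2+v2+ζ). The cut-off sweep re-runs
it with the accelerometer channel low-passed at 20, 15, 10 and 5 Hz
(force channel fixed at 20 Hz). Both are run at a 10-subject,
one-trial-per-speed scale (40 trials per condition), the scale at which
the filter sweep was originally reported; the full-cohort headline run
uses all 320 trials.

Two empirical caveats that the tests document explicitly, both
consequences of the synthetic data *satisfying* the model that real
runners violate:

* pinning p2/v2 shrinks the spread of the prediction error markedly and
  also lowers its median noticeably (by roughly 20% and more at some
  cohort scales): the pinned values coincide with the generating
  regime, so fixing them repairs exactly the non-identifiable
  directions. On real runners the same manipulation is reported to
  help only marginally, the model hypothesis itself being the limiting
  factor.
* lowering the accelerometer cut-off below 15 Hz *worsens* the median
  prediction error here (by tens of percent at 10 and 5 Hz): the
  aggressive filter removes genuine body-dynamics acceleration content
  along with the artifact, pulling the fitted parameters further from
  the generating regime. On real data the prediction error is
  hypothesis-dominated and the cut-off has little effect either way.
* the prediction-error medians rise from 2 to 5 m s⁻¹ overall but need
  not be strictly monotone across adjacent speeds: the truth anchors
  (notably λ and ζ) are themselves non-monotone in speed.

## Numerical and design choices

* Quartile method: linear interpolation (stated because conventions
  differ).
* Divergence penalty 1e6 (objective units), far above any physical RMSE.
* Per-trial fit seeds are derived deterministically from the trial's
  generation seed (Knuth multiplicative hash, kept below 2³¹), so batch
  results are byte-reproducible under a single cohort seed.
* The accelerometer-fit grid is the measured 100 Hz grid; a stance of
  duration T contributes ≈ 100·T + 1 samples (about 25), which is why
  eight parameters are never identifiable from the accelerometer route
  alone.
* Problem sizes in the shipped checks (320-trial headline cohort,
  20-trial recovery set, 40-trial experiment subcohorts) were chosen to
  keep a full desk run in the minutes range while preserving the
  study's grouping structure (80 trials per speed).

## Known limitations

* The optimiser is a local method; the restart policy explores, but
  does not enumerate, the solution set of a non-identifiable objective.
* Device internals (the real accelerometer's filter and clipping
  behaviour) are approximations; only the 50 Hz cut-off is emulated.
* The model is one-dimensional: only resultant-GRF magnitude is
  produced, with no directional load decomposition.
* Real-data ingestion is limited to the CSV + JSON sidecar contract;
  no C3D or vendor formats.
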