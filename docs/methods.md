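# Methods

## The model

### Plant

The hand is a planar point mass (default 1 kg) driven by a first-order
actuator that low-passes the commanded force with time constant
τ = 0.1 s.  The state is x = [p_x, p_y, v_x, v_y, f_x, f_y] (position,
velocity, actuator force).  Two external forces act on the lateral
axis: the constant background load φ (ramped linearly over 500 ms at
trial start, constant thereafter) and the velocity-dependent force
field F_x = θ·v_y.  The simulated window starts at the go cue with the
background fully ramped and the hand holding against it
(f_x = −φ), so trials begin at a true equilibrium.

Discretization (default dt = 10 ms) is the exact zero-order hold: the
matrix exponential of the continuous system.  Because the field
coupling v_y → v_x cannot be traversed twice by any path through the
state graph, exp(A_c(θ)·dt) is *exactly affine* in θ; the plant stores
A(θ) = A₀ + θ·ΔA (and B(θ) = B₀ + θ·ΔB), verified against a
high-accuracy integration oracle at 1e−9.  Two consequences: controller
synthesis at arbitrary θ̂ costs one matrix add, and the parameter
sensitivity ∂x̂_{t+1}/∂θ = ΔA·x̂ + ΔB·u used by the learning rule is
exact rather than a first-order dt·v_y/m approximation.

Since the field force is proportional to forward velocity it vanishes
while the hand rests in the start target, so the field is applied over
the whole simulated reach window rather than gated on a start-target
exit radius; a position gate would act only over the first ~5 mm of
movement while introducing an artificial model-mismatch transient for
the controller.  Catch trials set the field gain to zero (background
retained).

Noise: injected motor noise is white force noise on the actuator states
(per-step SD = `process_noise_scale`, in N).  The Kalman filter's
process-noise model additionally carries a small floor on position
(3 mm) and velocity (0.02 m/s) — a standard model-uncertainty term —
without which state errors caused by a misestimated field gain would be
unobservable to the filter and feedback correction would collapse.
Observation noise defaults to 1 mm-scale (`obs_noise_scale = 1e−3`).

### Controller and estimator

Certainty-equivalence LQG: the finite-horizon LQR gains solve the
backward Riccati recursion for the plant augmented with the *believed*
gain θ̂; the Kalman filter runs predict/update with the same
θ̂-augmented dynamics.  Control acts on goal-referenced coordinates
with the setpoint command u* = (−φ, 0) compensating the background at
the goal, which makes the error dynamics homogeneous.

Cost structure (defaults chosen so an unperturbed reach completes
within 600 ms with a bell-shaped speed profile, then holds):

| weight | value | role |
| --- | --- | --- |
| position | 1e4 | settle/terminal position accuracy |
| velocity | 1e2 | settle/terminal stopping |
| force | 1e−2 | settle/terminal actuator relaxation |
| effort r | 1e−4 | command penalty |
| lateral running | 1e2 | straightness during the movement phase |
| settle fraction | 0.75 | hold penalties begin at 75% of the horizon |

Horizon: 80 steps = 600 ms movement + 200 ms stabilization tail.  The
lateral running penalty sets the size of field-induced deviations; at
1e2 an unadapted reach against θ = 13 N·s/m shows an initial angle of
about 21° and a peak lateral deviation of about 29 mm, within the range
of human data for this field strength.  With θ̂ = θ the closed loop
lands within 1 mm of the goal with |initial angle| < 0.1°.

### Adaptation

The learning rule is a normalized least-squares identification step on
the Kalman innovation e and the exact sensitivity s:

    θ̂ ← θ̂ + γ · ⟨s, e⟩ / ⟨s, s⟩        (guarded as ⟨s,s⟩ → 0)

The normalization makes γ a dimensionless fraction of the *apparent
parameter error* corrected per update, which is what gives the printed
rate ranges meaning independently of plant units; the raw gradient form
⟨s, e⟩ (whose scale depends on state units) is available via
`normalized=False`.

Two processes share this rule:

* **Offline (γ₁)** — consolidates during each movement into an
  increment that only becomes effective at the next trial:
  θ̂_{k+1} = θ̂_k + Δ₁(T).  Its per-sample rate is
  γ₁·dt/τ₁ with integration timescale τ₁ = 35 ms, giving ≈1.5% of the
  error consolidated per trial at γ₁ = 1e−3.  γ₁ follows first-order
  dynamics from 1e−3 toward 0 with per-trial rate constant 0.02 (the
  decaying rate is what produces a residual asymptote in the initial
  angle rather than complete compensation).
* **Online (γ₂)** — a volatile within-trial increment Δ₂ that updates
  the controller (re-synthesized every step by default;
  `resynth_stride` trades accuracy for speed) and is discarded at trial
  end.  It integrates with a per-sample leak ρ = 0.2, so within a
  movement it equilibrates quickly to the *partial* correction
  γ₂/(γ₂+ρ) — about half the apparent error at the asymptotic
  γ₂ = 0.2.  γ₂ rises from 0 toward 0.2 with per-trial rate constant
  0.4.  Online updates engage only 250 ms after movement start,
  consistent with the latency of feedback adaptation; the initial-angle
  threshold is crossed before that (≈150 ms), keeping the initial angle
  a pure anticipation probe.
* Which first-order time constant (0.02 vs 0.4) belongs to which rate
  is a design choice here: 0.02 → γ₁ decay, 0.4 → γ₂ rise (slow
  forgetting of the offline memory, faster engagement of online
  adaptation); both are configurable.

Both model variants are driven by the *same* trial-by-trial memory
series θ̂_k, derived from the γ₁-only dynamics: in the online variant
γ₂ shapes within-trial corrections without altering the carried
memory.  This makes the two variants coincide exactly when γ₂ = 0 and
keeps the initial-angle series identical between them.

The leak and the offline integration timescale are the two constants
that position the model in the regime the paradigm probes — partial
online compensation (so the path length keeps a visible slow component)
and slow memory formation (so the slow rate is well separated from the
γ₂-engagement timescale).  Sessions with opposite field directions use
a single signed estimate by default (opposite trials partially unlearn
each other); `estimate_mode="per_cue"` keeps one estimate per cue.

## Simulated study conditions

The two-timescale analysis simulates 75-trial constant-field sessions
(θ = 13 N·s/m, φ = 4 N) with motor noise `process_noise_scale = 1.0` N,
chosen to produce trial-to-trial variability of ≈2.3° in the initial
angle and a few mm in path length, within the range of single-subject
human data.  The fitted series is the mean across 18 independent noisy
sessions, mirroring an 18-participant group average.  Under these
conditions (and with all learning-rate constants doubled or halved),
BIC selects the single-rate model for the initial angle and the
dual-rate model for the path length in the online+offline variant, and
single-rate for both in the offline variant; at baseline the two path
rates differ by more than a factor of 10 with non-overlapping Wald
intervals.

## Decay fitting

Internally both models use e^{−λx} with λ ≥ 0; reported rates are
β = −λ (negative = decay).  For the dual model β₁ is the slow and β₂
the fast rate.  For fixed rates the amplitudes are a linear subproblem
(variable projection); the rate(s) are multi-started on a grid
(fast ∈ {0.2, 0.5, 1, 2}, slow ∈ {0.005, 0.02, 0.05}) and the best
basins polished by bounded least squares to tolerance 1e−12.  Rates are
bounded at 3 per trial: at unit trial spacing a component decaying
faster than e^{−3} per step is within 5% of a single-point impulse and
is not identifiable.  Convergence is flagged from the optimizer status;
the BIC uses N·ln(RSS/N) + k·ln N (interpreting the residual sum in the
selection cost as a sum of squares, the form implied by the Gaussian
MLE machinery) with an RSS floor guarding perfect fits.  Ties and a
non-converged dual fall back to the single model.

Wald intervals come from the standard NLS covariance (σ² (JᵀJ)⁻¹ with
σ² = RSS/(N−k)) of the full parameter vector.  The participant
bootstrap resamples participants with replacement, averages, refits
(warm-started at the point fit), discards and counts non-converged
iterations, and reports percentile intervals.

## Synthetic cohorts

The kinematic generator produces 1 kHz trials: a minimum-jerk forward
profile (15 cm, 600 ms) with a 100 ms stationary hold before and after;
a lateral anticipatory lobe shaped like the forward speed profile and
*calibrated at the initial-angle threshold crossing*, so the scheduled
angle (asymptote + decaying component, one slow rate per trial series)
is exactly what the analysis pipeline measures — this makes noise-free
rate-recovery tests sharp to 1e−3; a corrective lobe confined to the
post-threshold phase whose amplitude decays with an additional fast
rate (feedback corrections act late, so it cannot contaminate the
initial angle); band-limited (10 Hz) positional noise anchored at zero
at trial start (trials begin with the cursor stabilized in the start
target); and a measured-force channel equal to the negated commanded
background plus noise (handle force is the reaction force).  Catch
trials carry a mirror-image anticipatory lobe.

What the generator does *not* emulate: within-trial feedback dynamics
(the corrective lobe is a fixed shape, not a closed loop), muscle
activity, trial-to-trial correlations beyond the scheduled decay, or
the magnitude-cue interference of the two-magnitude experiments.
Passing recovery tests therefore demonstrate correctness of the
analysis chain, not realism of every feature of recorded data.

`generate_decay_cohort` generates metric series directly from the
dual-rate law (defaults: rates −0.02 and −0.8, amplitudes 0.05,
per-point noise SD 0.003, participant-offset SD 0.005, n = 18) for
statistical recovery studies of the fitting machinery alone.

## Statistics

The analytic power formula 1 − Φ(z₁₋α − d̄√n/σ) uses the SD of the
paired differences; the pooled-SD effect size is a different
denominator, so power is never derived from the effect size.  Test
sidedness is always an explicit argument.  Mixed models are fitted by
REML (ML available) through statsmodels MixedLM with a participant
random intercept; reported t-statistics use the large-sample normal
approximation (n_obs is reported alongside).

## Numerical and engineering notes

* The Riccati recursion has a reference numpy implementation and a
  numba-compiled kernel (used by session simulation when numba is
  importable); the two are equivalence-tested to 1e−12.
* Session simulation with per-step controller re-synthesis runs at
  ≈1.5 s per 75-trial session; the test suite's study-scale checks are
  sized accordingly (18-session averages, 50 bootstrap cohorts, 1000
  Wald-coverage replicates).
* Trial tables round-trip through CSV at full precision (shortest
  round-trip floats on write, `float_precision="round_trip"` on read);
  parquet is available via file extension.
* Degenerate inputs are explicit errors: zero-variance paired tests,
  schedules with catch trials carrying a field, filters at or above
  Nyquist, trials that never leave the start target or never cross the
  angle threshold.

## Known limitations

* The LQG cost weights and noise magnitudes are declared defaults, not
  fitted quantities; the model reproduces the qualitative two-timescale
  signature, not quantitative human decay constants.
* The online-adaptation leak and latency are fixed constants of the
  model family, not estimated from data.
* Wald intervals for the fast rate undercover slightly (≈94% at the
  default cohort SNR) because the estimate is mildly biased at small
  effective sample sizes; the bootstrap inherits some of this bias.
* The magnitude-cue interference seen in the two-magnitude experiments
  is deliberately outside the model's scope.
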