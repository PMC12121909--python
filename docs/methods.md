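# Model and methods

`ecomotor` simulates whole-body squat-to-stand adaptation under a
velocity-proportional backward pull, using a hierarchy of four learners —
ecological cost arbitration, policy-gradient motor-plan search, adaptive
inverse dynamics, and prediction-error-tuned PD feedback — and provides the
measurement and statistics stack used to analyse such data (Trajectory
Area, Initial Trajectory Area, Smoothness, Co-Contraction; exponential
learning-curve fits; outcome-conditioned contrasts; cohort correlations).

## Body and environment

The body is a point mass m at the end of a massless, extensible leg hinged
at the ankle: generalized coordinates (r, θ) with r the leg extension and θ
the forward tilt from vertical, COM at (x, y) = (r sinθ, r cosθ).  A
prismatic actuator pushes along the leg and a rotational actuator applies
ankle torque.  While the COM rises, an external horizontal force

    F_pert = K · max(ẏ, 0) · m        (applied backward, K = 3 s⁻¹)

drags the body toward the heels.  The pull is clamped to upward COM motion;
its behaviour during descent is not defined by the paradigm and a backward
force during descent has no physical counterpart in the pulling mechanism.
Defaults: m = 77 kg, squat COM height 0.55 m, standing COM height 1.05 m
(0.5 m rise), movement duration 1.2 s, quiet-stance COM 0.05 m forward of
the ankle (the COM of a standing human projects near mid-foot).

Equations of motion are the point-mass Lagrangian dynamics with generalized
actuator forces and the external horizontal force; integration is
fixed-step RK4 at 1 ms with a zero-order-hold command per 5 ms control
tick.  Commands saturate at ±4000 N / ±400 N·m (generous; learning, not
clipping, shapes behaviour).

### Balance point and outcome rule

For a point mass with an external horizontal force F_x at the COM, the
moment balance about the ankle places the zero-moment point at

    x_zmp = x − y·(m·ẍ − F_x) / (m·(ÿ + g)).

The external-force term matters: a controller that perfectly cancels the
pull keeps ẍ ≈ 0, yet the ground must still supply the cancelling torque,
so the balance point sits ~K·ẏ·y/g behind the COM.  This is exactly why the
task forces a forward lean.  With F_x = 0 the expression reduces to the
textbook x − y·ẍ/(ÿ+g).

The model cannot step, so "needing a corrective step" is proxied by a
support-interval rule with the foot spanning [−0.08, +0.17] m around the
ankle: a trial fails if either (a) the COM itself leaves the support
interval for more than a 40 ms grace window (unrecoverable; its direction
names the fall — this is what makes an unannounced removal of the pull a
*forward* fall), or (b) the balance point leaves the interval for more than
the grace window (direction of the first sustained excursion), or (c) the
stand-up does not reach the standing height.  Everything else is a success.

## Motor plans

A plan is a spatial path x(y) — a natural cubic spline through the start,
three via points at 25/50/75 % of the rise, and the end — executed under a
fixed rest-to-rest rise pacing.  Only the three via-point x offsets are
learned, inside the constrained box v₁ ∈ [−2, 7] cm, v₂ ∈ [−2, 10] cm,
v₃ ∈ [−2, 12] cm (graded with height like the pull's tipping moment).

Two pacing/shape choices deserve explanation, both consequences of the
physics above:

* **Rise pacing.**  The pull's tipping moment scales with ẏ·y, so the rise
  is paced with ẏ ∝ 1/y (the squared height grows linearly between smooth
  cosine speed ramps of 28 % / 30 % of the duration): fast while the COM is
  low, slow while it is high.  This equalizes the backward COP shift over
  the movement — the profile a pulled human converges to.
* **Leaned finish.**  The path holds 70 % of the top via's offset through
  the final approach.  Returning the bow to the vertical line while the
  rise decelerates would demand forward COM acceleration exactly when the
  vertical ground reaction is smallest, throwing the balance point behind
  the heel; ending the recorded movement still slightly leaned (and
  settling afterwards) is what the support geometry permits.

Exploration noise on the three offsets is Gaussian with σ = 5 mm per via,
80 % of the variance shared along the plan: independent per-via jitter
would put high-curvature wiggles into the spline whose accelerations swing
the balance point by ±10 cm — lateral violence no motor system emits.

## The learning hierarchy

**Internal model.**  The feed-forward command is the exact unperturbed
inverse dynamics (closed form) plus a learnable additive term, linear in
the feature basis (ẏ, ẏ·sinθ, ẏ·r·cosθ) per actuator channel.  The basis is
the velocity-proportional-force family: the true pull is exactly
representable (weights converge to K·m), and because the features vanish
when the COM is not rising, the correction generalizes across plans instead
of memorising plan-specific residue.  Learning is normalized-LMS on the
command-space prediction error (feedback-error learning), one update per
control tick, η = 0.003.  The small η makes the model converge over ≈ 15
trials (this, not plan search, gates the first success) and wash out over
≈ 10–15 unperturbed trials during de-adaptation.  A running RMS of the
prediction error in acceleration-equivalent units is the model-confidence
signal.

**Feedback.**  Fixed Cartesian PD gains (kp = 1500 N/m, kd = 250 N·s/m per
axis) act on COM tracking error, mapped to actuator space by the
configuration Jacobian transpose, all scaled by a single multiplier
g = min(cap, c·trace) with c = 1.5 per (m/s²) and cap 3.  Gains are thus
inversely tied to internal-model accuracy: the multiplier rises when the
environment changes (perturbation onset, catch trial) and decays toward
zero as the model converges, with no direct dependence on trial outcome.

**Plan policy.**  REINFORCE on the via offsets with an EMA reward baseline
(decay 0.9) and learning rate 8×10⁻⁶ — chosen so the effective step
α·|advantage|/σ² stays below ~0.3 of the sample deviation; larger rates
overshoot every sample and churn the mean.  The first reward only seeds the
baseline.  In safe mode the mean is refined on failures only; plan change
on successful safe-mode trials is limited to the decaying safety bias
(matching the observation that plans change on failed, not successful,
trials), while the efficient mode updates on every trial.

**Ecological control.**  Learning starts in *safe* mode: the cost is the
backward excursion of the balance point, max(0, −min_t zmp / 0.08) — zero
whenever the balance point stays forward of the ankle (so there is no
gradient toward pinning it at the toe, and an unperturbed learner does not
drift), 1 when pinned at the heel.  After a per-run confidence threshold of
accumulated successes — drawn once from Normal(50, 50), truncated below at
1 — the learner switches to *efficient* mode and minimises squared
normalized actuator effort instead.  The composite reward is
`success_bonus·1[success] − w·active_cost` with bonus 1, w_safety 0.6,
w_effort 0.4 (cost terms O(0.1–1)).  On any failure the learner reverts to
safe mode (confidence progress retained) and:

* restores the policy mean to the remembered safe plan, *after* nudging
  that memory against the direction of the fall by (3, 5, 6) mm per via —
  failure-driven plan correction keeps the memory inside the feasible band
  even as the sharpening internal model shifts that band;
* sets the sampling bias: a backward fall raises the forward bias (by 0.2
  per fall while no safe plan exists, to 0.1 after a restore), a forward
  fall clears it.  The bias interpolates the sampling centre toward a
  hard-wired safe posture shape (5, 9, 10) cm — full bias centres sampling
  on that shape no matter where the mean has wandered.

On safe-mode successes the safe-plan memory consolidates: it moves 30 % of
the way toward the executed plan, converging to the centroid of recent safe
successes rather than chasing the latest (possibly marginal) one.

## Protocol

Per simulated participant: 15 unperturbed baseline trials (habitual
stand-ups; no policy learning — they exercise the movement and store the
unperturbed plan memory), a perturbation block until 60 successes (capped
at 300 trials; an exhausted cap marks the run not completed), one
unannounced catch trial (pull silently off), five further perturbed trials,
then 15 announced de-adaptation trials for which the plan is reset to the
unperturbed memory and the internal-model correction is shifted 10 % toward
zero (ρ = 0.1; chosen so the first de-adaptation trial typically fails —
the residual compensation must be washed out by learning, which is the
point of the block).  Population runs use consecutive seeds; per-trial
curves are averaged on the normalized 84-trial grid
(trial/N × 84, rounded to integer bins).

## Measures

* Trajectories are translated to the origin and scaled isotropically so the
  rise is 0.5 m (the source convention states the vertical scaling only;
  isotropic scaling keeps areas commensurable across bodies).
* **TA** = ∫ x dy over the rise (trapezoid along the path, cut by linear
  interpolation at the bound), in cm²; positive = forward.  **ITA** is the
  same integral up to y = 2.5 cm (5 % of the normalized rise).
* **SM** = (∫ jerk² dt)·D³/v̄²; jerk via Savitzky–Golay triple
  differentiation (window 11, order 5).  Lower is smoother; an ideal 1-D
  minimum-jerk movement scores exactly 720, which the tests use as the
  closed-form oracle.
* **COC** = iEMG(vastus medialis)/iEMG(biceps femoris): zero-lag 4th-order
  Butterworth band-pass 20–500 Hz (upper edge capped just below Nyquist at
  1 kHz sampling), full-wave rectification, 50 ms moving-RMS envelope,
  trapezoid integration, quotient.

## Analysis

Learning curves are fitted with a·e^(−x/b)+c by multi-start nonlinear least
squares (starts jittered ×0.25…4 plus a negative-b start so runaway time
constants are recognisable); b < 0 flags `negative_b`, b > 10× the x-span
flags `linear_fit` (exponential indistinguishable from a line on the
window), both excluding the plateau.  The plateau — 95 % of the asymptotic
change — is x = b·ln 20 exactly.  Outcome contrasts sum metric changes over
consecutive-success (S-S) and success–failure–success (S-F-S) pairs per
run, excluding pairs whose intervening failures include a forward step, and
compare the per-run sums with a paired t-test.  De-adaptation is summarised
by RD = 1 − (A_D1 − A_B)/(A_C − A_B).  Cohorts are compared by all-pairs
Pearson correlation on the 84-trial grid with per-reference min/mean/max r
and non-significant counts; Benjamini–Hochberg and Bonferroni adjustments
are available for multi-test tables.  Repeated-measures ANOVA is not
reimplemented; the paired-contrast battery covers the same comparisons.

## Synthetic fixtures

`ecomotor.fixtures` generates human-like trial series without running the
simulator: parabolic-bow trajectories on a minimum-jerk rise whose bow
amplitude follows a prescribed exponential trend plus Gaussian noise,
failures drawn from a per-trial probability curve (failed trials bent
backward), and noisy antagonist EMG bursts whose activity ratio is elevated
on and immediately after failures.  These exercise every metric and
analysis path deterministically.  They emulate the *shape* of adaptation
data — they carry none of the biomechanics, so tests passing on fixtures
validate the measurement and statistics code, not the simulator (the
simulator is validated by the population-level acceptance checks).

## Reference optima

A small direct-collocation program (40 nodes, fixed 1.2 s, L-BFGS-B on a
penalty formulation) computes point-mass stand-up trajectories that either
keep the COP as far forward as possible while avoiding provoking the
velocity-proportional pull (max safety) or minimise squared actuator effort
(min energy).  The safety optimum arches forward (larger TA and ITA); the
energy optimum stays nearly straight and carries the larger peak pull.
Only these ordinal properties are asserted.

## Numerical and scale choices

Simulations run at 1 ms dynamics / 5 ms control steps; a full run is ~120
trials and takes ~2.5 s, a 60-run population ~2.5–3 min on one core.  The
test suite uses a shared 60-run population for the cohort-level checks and
smaller replicate counts (10–100) for recovery studies.

## Known limitations

* The first-success trial number is far less variable across runs (SD ≈
  0.4) than the reference cohort statistics (SD ≈ 2.55): every simulated
  participant shares identical learning rates, so discovery timing is
  gated almost deterministically by internal-model convergence.  Per-run
  heterogeneity in η or bias gain would widen it; none is modelled.
* Trajectory Area does not return fully to baseline within the 15
  de-adaptation trials (~70 cm² residual vs ~380 cm² adapted): with ρ =
  0.1 most of the washout is left to learning, and 15 trials remove ~90 %
  of the correction.
* Muscle-level impedance/co-contraction control is not modelled; simulated
  trials therefore carry no EMG, and Co-Contraction is exercised on the
  synthetic fixtures only.
* The fall rule (support interval, grace window) is a proxy; no stepping
  or contact mechanics are simulated.
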