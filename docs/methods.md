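# Methods notes

## Plant and state space

The hand is a planar point mass (m = 1.1 kg) with intrinsic viscosity
b = 7 N·s/m, driven by two orthogonal force actuators behind a first-order
low-pass "muscle" filter with time constant τ = 0.05 s. The state stacks
position, velocity, actuator force and target position (eight components);
keeping the target in the state lets one quadratic form express tracking
error and makes a cursor/target jump an instantaneous state change. The
continuous dynamics are discretized by forward Euler at dt = 10 ms, the
simulation step used throughout.

Motor noise is control-dependent: the applied control is (I + C)u with the
2×2 matrix C drawn elementwise i.i.d. N(0, c²) each step. Observations are
position, velocity and force (the target is task knowledge, not a sensory
channel) with additive noise. Neither noise magnitude is fixed by published
values; the defaults are c = 0.5 and observation noise small relative to
typical state magnitudes (0.001 m, 0.01 m/s, 0.05 N). All headline
simulations are noise-free mean rollouts, but c matters indirectly because
the *gains* of the finite-horizon solver account for it: with c = 0.5 the
fitted baseline movement lands at ~910 ms, with c = 0 near ~780 ms, so the
noise level effectively sets how conservative (slow) optimal movements are.

## Cost conventions and units

The plant integrates SI states, but cost weights are the dimensionless
numbers of the task description, which states distances in cm. Position
errors and speeds therefore enter the cost in cm and cm/s (implemented as a
×100 scale inside the terminal-cost builder), forces and controls in N.
This convention was pinned down by behaviour, not taste: with SI-unit costs
the optimal baseline reach stops 1.9 cm short of the target (verified
against an independent direct quadratic-program solution of the same LQ
problem), while with task-unit costs it arrives exactly and its peak speed
at the fitted duration matches the behavioral targets.

The terminal cost is Σ_axis (wp·(p−p*))² + wv·‖v‖² + wf·‖f‖² applied at the
final step only (finite-horizon models), at the look-ahead boundary
(receding horizon), or at every step (infinite horizon). Defaults:
wp = [0.5, 1], wv = 0.02, wf = 2 with base activation cost R = 1e-5 for the
stop-instruction finite-horizon models; the hit / fast-hit instruction
variants divide wv and wf by 4 / 10 with stated durations 800 / 750 ms.

## Coupled gain solver

With multiplicative noise, control and estimation do not separate. The
solver alternates a backward control pass (cost-to-go matrices for the true
state and for the estimation error) and a forward estimator pass
(error covariance, uncentred estimate second moment, cross term) until the
largest relative change of any gain falls below tolerance (default 1e-9;
the criterion is relative so it is invariant to the overall cost scale).
Because every element of C is i.i.d., the multiplicative-noise sums reduce
to closed forms — c²·tr(B'(Sˣ+Sᵉ)B)·I on the control side and
c²·tr(LΣ̂L')·BB' on the filter side — keeping each sweep at a handful of
8×8 products. A numba-compiled kernel implements the same loop ~7× faster;
the test suite asserts the two paths agree bit-for-bit. The estimate second
moment is uncentred (Σ̂₀ = x₀x₀'): noise scales with the *magnitude* of the
planned control, mean included, so the gains depend on the movement being
planned. The state estimate itself is initialized at the true initial state
(the participant knows where they start and where the target is).

Degenerate inputs: noiseless observation channels make the innovation
covariance singular; a relative ridge of 1e-14 on its diagonal keeps the
filter solve defined (and yields K → 0, the correct limit). Tie-breaking
never arises — the iteration is a deterministic fixed-point scheme.

## Condition fitting

Movement duration N and the activation-cost schedule are not free inputs:
they are fitted so the mean rollout's peak forward speed and peak location
match the task targets (50 cm/s at 50 / 66 / 33 % of the 25 cm reach),
maximizing a Gaussian log-likelihood with sd 4 cm/s on speed and 2.5 % on
location — half the behavioral acceptance bands. The activation schedule
R(t) = R_base·s(t)/mean(s), s(t) = exp((p·t+q)/r), is normalized by its
mean, so every condition is exactly equally "effortful"; the normalization
also cancels q exactly and leaves only p/r identifiable, so the optimizer
searches (N, p) with q = 0, r = 1 as reference values. The baseline
condition's schedule is constant by construction, so only N is optimized
there — which is why repeated baseline fits agree to the step while the
skewed conditions show run-to-run spread. The horizon enters the search
continuously, with the log-likelihood linearly interpolated between
neighbouring whole-step horizons to remove plateaus that stall the simplex.
The optimizer is seeded random-restart Nelder-Mead within bounds
(N ∈ [0.6, 1.6] s, |p| ≤ 10 s⁻¹), restarts starting on the a-priori correct
tilt side (delaying the peak requires penalizing early activation). Any
bounded derivative-free method satisfies the same contract. Fit-stage
solves run at tolerance 1e-4 with a 60-sweep cap — the peak kinematics are
stable to four decimals at that setting.

## Simulated feedback intensities

Classical model: for every onset step t_p the target is shifted 2 cm
laterally at t_p + 120 ms (the visuomotor delay) and the intensity is the
mean lateral force over [t_p+130, t_p+180] ms, differenced against the
unperturbed rollout and signed toward the jump; onsets whose window
outlasts the movement score exactly zero. Time-to-target model: the
pre-perturbation movement is the unperturbed one (the controller stays
naive); from the state 120 ms after crossing the onset location a fresh
finite-horizon problem is solved toward the shifted target with horizon
equal to the *behaviorally observed* time-to-target, and intensity is the
mean lateral force over 10–60 ms of that re-planned movement, differenced
against an identical re-plan without the shift (for a straight reach both
baselines are ≈ 0, so the differencing convention is immaterial).
Behavioral times-to-target are inputs to this model, not outputs — here
they come from the synthetic ground-truth tables. The re-planned problem
uses the constant base activation cost: it is a fresh movement, not a
continuation of the condition's schedule. Millisecond windows map to steps
by rounding at dt = 10 ms ([130, 180] ms ⇒ steps 13–18 inclusive).

With c > 0 the re-planned subproblem's gains differ slightly from the tail
of the original problem (the uncentred moment restarts at the perturbation
state), so the "identical subproblem" equivalence between the two models
holds exactly only under certainty equivalence; the test suite checks it at
c = 0.

## Receding- and infinite-horizon variants

Both make duration an output: the rollout continues until the cursor is
within 0.4 cm of the target and stays there, without overshooting, for
600 ms. The receding controller re-solves a 500 ms finite-horizon problem
(terminal weights wp = [5,5], wv = 0.05, wf = 5; R = 3e-6) from the current
state every 10 ms and applies the first control; the infinite-horizon
controller applies the stationary gain of the constant-per-step cost
problem (weight ratios wp = [1,1], wv = 0.02, wf = 0; R = 0.002).
Perturbations shift the target 2 cm laterally 120 ms after the forward
position passes the onset location; time-to-target is measured from the
shift instant to the first sample within the 0.4 cm radius. The model
"cursor" is the hand — cursor kinematics proved irrelevant to the feedback
intensities, and the modelled conditions have coincident cursor and hand.

Two design choices deserve emphasis. First, both variants compute their
gains by certainty equivalence (the multiplicative-noise terms are dropped
from the gain computation; noise still acts in stochastic rollouts). With
the very small activation costs of these variants, the noise-coupled
coordinate descent has a second, degenerate fixed point at cruising states
in which control is judged "too noisy to use" and the gains collapse to
near zero, leaving the plant coasting; certainty equivalence avoids that
pathology, and as a side effect makes the receding sub-problem gains
state-independent, so one solve serves an entire run. Second, the
infinite-horizon cost magnitude is calibrated, not copied: the published
weight values for the non-finite variants were selected to make simulated
movement durations match the behavioral ones, and under this
implementation the nominal values produce a 620 ms movement instead of the
~930 ms baseline. The package therefore keeps the published weight *ratios*
and bisects a single overall state-cost scale until the unperturbed
movement duration equals the behavioral baseline (932 ms); times-to-target
are then reported as they fall. The receding-horizon costs reproduce the
behavioral durations as published (unperturbed 910 ms, perturbed 930–1170
ms rising with onset location) and are used verbatim.

The stationary gain is computed by value iteration of the backward Riccati
recursion with the stage cost at every step, declaring convergence only
when both the gain and the value matrix are stationary (the gain alone is
momentarily zero while the position cost has not yet propagated into the
actuated subspace). The stationary Kalman gain uses the filter Riccati
fixed point with the control-noise injection frozen at a reference drive —
with c = 0 it correctly collapses to K = 0.

## Tuning function

G(t) = min( β/(t−t₁)², α/(1+exp(−(t−t₀)/τ_l)) ). The inverse-square limb is
the constant-force point-mass law F = 2md/t² up to the (β, t₁)
reparameterization — β = 2md, t₁ = 0 recovers it exactly. The printed form
of the first limb is typographically ambiguous; the inverse-square reading
is forced by its derivation from the physics and by the decay of intensity
at long times-to-target. Fitting is maximum likelihood under homoscedastic
Gaussian residuals with the sd profiled out (equivalently least squares),
by the same bounded Nelder-Mead machinery with a final polish restart;
fits whose points all lie on one limb are flagged unidentifiable.

## Behavioral analysis

Force and kinematic series (1 kHz) are filtered with a zero-phase
Butterworth low-pass, total order 10 realized as a 5th-order filter run
forward and backward, 40 Hz cutoff. Feedback intensity is the mean of
(F_left − F_right)/2 over 180–230 ms after the perturbation, the divisor
making the value the corrective force per single perturbation (it is a
parameter, for bit-compatibility with the undivided convention). Response
onsets: the area under the ROC curve between left- and right-perturbation
force samples is computed each millisecond from −50 ms; scanning stops at
the first 10 consecutive ms above 0.75; max(0.5, k(t−τ_b)) is fitted to the
aROC series up to that point by least squares with a 1 ms breakpoint grid
refined to 0.1 ms, and the onset is the breakpoint. The aROC depends only
on ranks, so the onset is invariant to any common monotone transform of
the forces. Durations and times-to-target come from maintained trials:
first interception within the 0.6 cm behavioral radius; for unperturbed
trials the time-to-target at a location is duration minus that location's
crossing time. Trials that never intercept are excluded with a log entry,
as are blocks missing one side of a left/right pair.

## Synthetic cohort

The generator emulates the session structure (five conditions; blocks of
22 trials: five locations × two directions + zero perturbation, as channel
and as maintained trials; 1 kHz). Hand kinematic templates are time-warped
minimum-jerk reaches whose velocity peak sits at the condition's location
(late-peak profiles are the time-mirror of the matching early-peak ones);
durations default to 930 / 1050 / 1130 ms. Ground-truth times-to-target are
remaining template time at crossing plus a location-dependent extension
(50–260 ms, largest near the target). Channel forces are a 250 ms
minimum-jerk force pulse starting at onset + latency (140 ms), scaled so
its mean over 180–230 ms equals the ground-truth tuning value *exactly* —
noiseless datasets therefore round-trip through the analysis to machine
precision — plus white noise (sd 0.05 N). The default tuning curve ties
β to the point-mass law for the 2 cm jump (β = 2·1.1·0.02). Maintained
trials re-plan a straight minimum-jerk cursor approach whose radius
crossing lands exactly on the scripted time-to-target.

What the generator does **not** emulate: trial-to-trial kinematic
variability, learning or fatigue across blocks (the maintained trials of
the experiment were designed to hold intensities stationary), biomechanical
coupling between axes, realistic single-trial force shapes (only window
means are matched), or the velocity discontinuity smoothing at the re-plan
instant. Passing round-trip tests therefore certify the pipeline's
bookkeeping and estimators, not its robustness to those phenomena in real
recordings.

## Model comparison

Each model contributes one predicted intensity per (participant, condition,
location) cell; likelihoods are independent Gaussians with the residual sd
profiled out, so BIC = k·ln(n) − 2·logL depends on the data through the SSR
alone. Δ BIC is reported as BIC(reference) − BIC(model): positive favours
the model. Parameter counts: classical and time-to-target models carry the
condition-fit parameters (duration and tilt for each of three conditions,
k = 6), the receding model uses published constants only (k = 0), the
infinite model its calibrated scale (k = 1), the tuning curve its five
shape parameters. Because the controller models are fitted to kinematics
and never to intensity magnitudes, each LQG model additionally receives one
least-squares output gain before scoring (counted in k): the comparison is
about the pattern of intensities across conditions and locations, which is
where the models genuinely differ.

## Problem sizes and runtimes

The study-scale simulations (93–130 step horizons, five locations, ten
optimizer runs per condition) run end-to-end in minutes on one CPU; the
synthetic cohorts used by the tests are 1–4 participants × 2–10 blocks,
chosen as the smallest sizes at which the estimator-closure checks are
meaningful. The acceptance script uses the full ten-run fitting protocol.

## Known limitations

* The exact noise magnitudes (c, observation sds) of the source study are
  unknown; gains, and thus fitted durations, shift by a few percent across
  plausible choices.
* The non-finite variants' times-to-target land ~5–10 % short of the
  published sequences under every event convention we examined (first
  interception vs hold-entry, onset at crossing vs at shift, radii
  0.1–0.6 cm); the discrepancy is systematic (their late-location
  corrections are relatively slower than ours) and unresolved.
* The time-to-target model takes behavioral times-to-target as inputs; it
  does not predict the post-perturbation duration extension itself.
* Fits on the skewed conditions sit on a likelihood ridge (several
  (N, tilt) pairs satisfy the kinematic targets almost equally well), so
  fitted durations there have genuine run-to-run spread; reported values
  are means over ten seeded runs.
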