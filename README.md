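# reachofc

Optimal feedback control models of visuomotor feedback responses in planar
reaching.

When the cursor representing your hand jumps sideways mid-reach, you push
back within ~140 ms — and the vigour of that push depends on where in the
movement the jump happens. This package implements a family of stochastic
optimal control models of that regulation and the analysis pipeline that
measures it, for researchers in computational motor control:

* a discrete-time linear plant (point-mass hand, m = 1.1 kg, intrinsic
  viscosity b = 7 N·s/m, first-order muscle filter τ = 50 ms) driven by a
  linear-quadratic-Gaussian (LQG) controller with *control-dependent* motor
  noise, solved by the coupled coordinate-descent iteration of the control
  and Kalman gains (the classical separation principle fails under
  multiplicative noise);
* four controller variants: the **classical** finite-horizon model, a
  **time-to-target** model that re-plans the post-perturbation movement with
  the behaviorally observed time-to-target as its horizon, and
  **receding-horizon** (Th = 500 ms) and **infinite-horizon** (stationary
  gain) controllers whose movement durations are outputs rather than inputs;
* the **tuning function** G(t) = min( β/(t−t₁)², α/(1+exp(−(t−t₀)/τ)) )
  mapping time-to-target t to feedback intensity — its inverse-square limb
  is point-mass physics (F = 2md/t²), its logistic limb suppresses
  corrections near the deadline;
* a behavioral pipeline (zero-phase Butterworth filtering, left/right
  channel-force differencing over the 180–230 ms window, aROC response-onset
  detection, movement-duration and time-to-target extraction) plus a
  synthetic-participant generator with exact ground truth, so the entire
  pipeline is testable without recorded data;
* BIC / sum-of-squared-residual model comparison.

## Worked example

Fit the baseline condition (peak speed 50 cm/s at mid-reach) and probe the
fitted movement with a virtual 2 cm target jump at every step:

```python
from reachofc import (PlantParams, build_plant, fit_kinematic_condition,
                      classical_intensity_profile)

system = build_plant(PlantParams())          # m=1.1 kg, b=7 N·s/m, τ=50 ms
fit = fit_kinematic_condition(system, 0.5, 50.0, seed=3)
print(f"fitted duration: {fit.duration_ms:.0f} ms")
prof = classical_intensity_profile(system, fit)
peak = prof.intensities.argmax()
print(f"peak simulated intensity {prof.intensities.max():.2f} N "
      f"at {peak * 10} ms into the movement")
```

prints

```
fitted duration: 910 ms
peak simulated intensity 4.40 N at 580 ms into the movement
```

i.e. the optimizer chooses a ~0.9 s movement for the 25 cm reach, and the
simulated corrective response is weak at the start, strongest past
mid-movement, and collapses near the target — the bell-like intensity
profile that, re-expressed against time-to-target, collapses onto a single
tuning curve across movement speeds and skews (run
`analysis/04_peak_velocity_sweep.py`).

The numbered scripts under `analysis/` walk through the full study:
condition fits, classical and time-to-target intensities, the peak-velocity
sweep, the receding/infinite-horizon simulations, the behavioral pipeline on
a synthetic cohort, and the model comparison. Each writes its tables to
`results/`.

## Layout

```
src/reachofc/     plant.py, lqg.py      LQG plant + coupled gain solver
                  design.py             task geometry, cursor-gain maps
                  finite_horizon.py     classical & time-to-target models
                  horizons.py           receding & infinite horizon models
                  tuning.py             time-to-target tuning function
                  behavior.py           trial-level behavioral analysis
                  synthetic.py          synthetic-participant generator
                  comparison.py         BIC / SSR model comparison
analysis/         numbered study scripts (write to results/)
docs/methods.md   modelling and analysis notes
```
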