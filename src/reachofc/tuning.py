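"""The time-to-target tuning function for feedback intensity.

Across movements with very different kinematics, simulated (and measured)
visuomotor feedback intensities collapse onto one curve when expressed
against the time left to reach the target.  The curve is the minimum of two
limbs:

* a *squared-hyperbolic* limb ``beta / (t - t1)^2``.  This is plain
  point-mass physics: the constant force that carries a mass m over the
  remaining lateral distance d in time t (from rest) is F = 2 m d / t^2, so
  corrective force must grow as the inverse square of the time available;
* a *logistic* limb ``alpha / (1 + exp(-(t - t0)/tau))`` that suppresses
  responses when very little time remains -- close to the deadline the
  controller is stopping, not correcting.

The hyperbolic limb dominates (and decays) at long times-to-target, the
logistic suppression at short ones; the curve peaks at their crossover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import optim


@dataclass(frozen=True)
class TuningParams:
    """Parameters of the intensity-vs-time-to-target curve.

    beta : N s^2, scale of the hyperbolic limb; t1 : s, its time offset;
    alpha : N, asymptote of the logistic limb; t0 : s, logistic midpoint;
    tau_l : s, logistic width.
    """

    beta: float
    t1: float
    alpha: float
    t0: float
    tau_l: float

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.alpha <= 0 or self.tau_l <= 0:
            raise ValueError("beta, alpha and tau_l must be positive")


def eval_tuning(t, params: TuningParams):
    """Evaluate the tuning curve at time-to-target ``t`` (s, > t1)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= params.t1):
        raise ValueError(f"time-to-target must exceed t1={params.t1}")
    hyper = params.beta / (t - params.t1) ** 2
    expo = np.clip(-(t - params.t0) / params.tau_l, -700.0, 700.0)
    logistic = params.alpha / (1.0 + np.exp(expo))
    out = np.minimum(hyper, logistic)
    return out if out.ndim else float(out)


def point_mass_force(m: float, d: float, t: float) -> float:
    """Constant force carrying a point mass m over distance d in time t,
    starting from rest: F = 2 m d / t^2."""
    if t <= 0:
        raise ValueError("time must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 2.0 * m * d / t**2


@dataclass(frozen=True)
class TuningFit:
    params: TuningParams
    log_lik: float
    sigma: float
    identifiable: bool
    n_points: int


#: box constraints for the five curve parameters (beta, t1, alpha, t0, tau_l)
TUNING_BOUNDS = np.array(
    [[1e-4, 10.0], [-0.5, 0.3], [0.01, 10.0], [0.0, 1.5], [1e-3, 0.5]]
)


def fit_tuning(
    times,
    intensities,
    seed: int,
    n_restarts: int = 8,
    maxfev: int = 2000,
) -> TuningFit:
    """Maximum-likelihood fit of the tuning curve to (t, intensity) points.

    Residuals are modelled as homoscedastic Gaussians with the standard
    deviation profiled out, so the optimization minimizes the sum of squared
    residuals; the returned log-likelihood is the profiled Gaussian one.
    Warns (and flags the result) when every point lies on a single limb of
    the fitted curve, in which case the other limb's parameters are not
    identified.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and intensities must be 1-D and aligned")
    n = t.size
    if n < 5:
        raise ValueError("need at least 5 points to fit 5 parameters")

    def neg_ssr(theta) -> float:
        params = TuningParams(*theta)
        if np.any(t <= params.t1):
            return -1e12  # finite penalty keeps the simplex well-defined
        resid = y - eval_tuning(t, params)
        return -float(resid @ resid)

    res = optim.maximize(
        neg_ssr, TUNING_BOUNDS, seed=seed, n_restarts=n_restarts, maxfev=maxfev
    )
    params = TuningParams(*res.x)
    ssr = -res.fun
    sigma = float(np.sqrt(max(ssr, 1e-300) / n))
    log_lik = -0.5 * n * (np.log(2 * np.pi * sigma**2) + 1.0)

    hyper = params.beta / (t - params.t1) ** 2
    logistic = params.alpha / (1.0 + np.exp(-(t - params.t0) / params.tau_l))
    on_hyper = hyper <= logistic
    identifiable = bool(on_hyper.any() and (~on_hyper).any())
    if not identifiable:
        limb = "hyperbolic" if on_hyper.all() else "logistic"
        warnings.warn(
            f"all fitted points lie on the {limb} limb; the other limb's "
            "parameters are not identified",
            RuntimeWarning,
            stacklevel=2,
        )
    return TuningFit(
        params=params,
        log_lik=log_lik,
        sigma=sigma,
        identifiable=identifiable,
        n_points=n,
    )
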