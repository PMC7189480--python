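"""Seeded bounded derivative-free maximization.

All model fits in this package (condition kinematics, tuning curve) share one
optimizer: Nelder-Mead restarted from seeded uniform draws within the bounds,
with the best restart returned.  Any bounded derivative-free method satisfies
the fitting contracts; Nelder-Mead keeps the dependency surface at scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class OptResult:
    x: np.ndarray
    fun: float  # maximized objective value
    n_evals: int
    seed: int


def maximize(
    objective,
    bounds,
    seed: int,
    n_restarts: int = 3,
    maxfev: int = 400,
    x0: np.ndarray | None = None,
    start_bounds=None,
    xatol: float = 1e-4,
    fatol: float = 1e-7,
) -> OptResult:
    """Maximize ``objective`` within box ``bounds``.

    Restart starting points are drawn uniformly from ``start_bounds`` (by
    default the full box) using a generator seeded with ``seed``, so results
    are reproducible; an explicit ``x0`` replaces the first draw.  Failure of
    every restart raises, carrying the best point seen so far.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    sb = bounds if start_bounds is None else np.asarray(start_bounds, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    n_evals = 0
    for i in range(n_restarts):
        start = x0 if (i == 0 and x0 is not None) else rng.uniform(sb[:, 0], sb[:, 1])
        res = optimize.minimize(
            lambda x: -objective(x),
            start,
            method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
        )
        n_evals += res.nfev
        if best is None or -res.fun > best[1]:
            best = (np.clip(res.x, lo, hi), -res.fun)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(f"optimization failed; best so far {best}")
    # polish: restart the simplex from the best point found (a fresh simplex
    # escapes the collapsed shape a converged run ends with)
    res = optimize.minimize(
        lambda x: -objective(x),
        best[0],
        method="Nelder-Mead",
        bounds=optimize.Bounds(lo, hi),
        options={"maxfev": max(maxfev // 2, 40), "xatol": xatol / 10, "fatol": fatol / 10},
    )
    n_evals += res.nfev
    if -res.fun > best[1]:
        best = (np.clip(res.x, lo, hi), -res.fun)
    return OptResult(x=best[0], fun=best[1], n_evals=n_evals, seed=seed)
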