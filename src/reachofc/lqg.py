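"""Finite-horizon LQG with control-dependent noise.

With multiplicative (signal-dependent) motor noise the classical separation
principle fails: the optimal feedback gains depend on the filter and vice
versa.  Following the coordinate-descent scheme of Todorov (2005), the solver
alternates

  * a backward pass that computes the control gains ``L_t`` given the current
    Kalman gains, propagating two cost-to-go matrices: ``S_x`` (cost of the
    true state) and ``S_e`` (extra cost incurred by estimation error), and
  * a forward pass that computes the Kalman gains ``K_t`` given the control
    gains, propagating the estimation-error covariance, the (uncentred)
    second moment of the state estimate, and their cross term,

until the gains stop changing.  Because every element of the 2x2 control
noise matrix is i.i.d. with standard deviation ``c``, the multiplicative
noise sums collapse to closed forms:

    sum_i C_i' S C_i          = c^2 * tr(B' S B) * I_2
    sum_i C_i u u' C_i' (E..) = c^2 * tr(L Sig_xhat L') * B B'

which keeps each sweep at a handful of 8x8 products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .plant import N_CONTROLS, N_OBS, N_STATES, LinearSystem, POS, TGT, VEL, FRC


@dataclass(frozen=True)
class CostSchedule:
    """Per-step quadratic costs for an ``N``-step problem.

    ``Q`` has shape (N+1, 8, 8) (state cost at every step including the
    terminal one); ``R`` has shape (N,) and holds the scalar activation cost
    applied as ``R[t] * ||u_t||^2``.
    """

    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if Q.ndim != 3 or Q.shape[1:] != (N_STATES, N_STATES):
            raise ValueError("Q must have shape (N+1, 8, 8)")
        if R.ndim != 1 or R.shape[0] != Q.shape[0] - 1:
            raise ValueError("R must have shape (N,) consistent with Q")
        if np.any(R <= 0):
            raise ValueError("activation costs must be strictly positive")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "R", R)

    @property
    def horizon(self) -> int:
        return self.R.shape[0]


@dataclass(frozen=True)
class OptimalController:
    """Feedback and filter gain sequences returned by the solver."""

    L: np.ndarray  # (N, 2, 8)
    K: np.ndarray  # (N, 8, 6)
    converged: bool
    iterations: int
    gain_delta: float

    @property
    def horizon(self) -> int:
        return self.L.shape[0]


@dataclass(frozen=True)
class Trajectory:
    """A simulated rollout: N+1 states, N controls, times on the dt grid."""

    states: np.ndarray
    controls: np.ndarray
    times: np.ndarray
    dt: float

    @property
    def positions(self) -> np.ndarray:
        return self.states[:, POS]

    @property
    def velocities(self) -> np.ndarray:
        return self.states[:, VEL]

    @property
    def forces(self) -> np.ndarray:
        return self.states[:, FRC]

    @property
    def targets(self) -> np.ndarray:
        return self.states[:, TGT]


def _control_pass(system: LinearSystem, costs: CostSchedule, K: np.ndarray):
    """Backward sweep: control gains given Kalman gains."""
    A, B, H = system.A, system.B, system.H
    c2 = system.c_scale**2
    N = costs.horizon
    L = np.empty((N, N_CONTROLS, N_STATES))
    S_x = costs.Q[N].copy()
    S_e = np.zeros((N_STATES, N_STATES))
    for t in range(N - 1, -1, -1):
        BtS = B.T @ S_x
        G = costs.R[t] * np.eye(N_CONTROLS) + BtS @ B
        if c2 > 0:
            G = G + c2 * np.trace(B.T @ (S_x + S_e) @ B) * np.eye(N_CONTROLS)
        L[t] = np.linalg.solve(G, BtS @ A)
        AKH = A - K[t] @ H
        S_e_new = A.T @ S_x @ B @ L[t] + AKH.T @ S_e @ AKH
        S_x = costs.Q[t] + A.T @ S_x @ (A - B @ L[t])
        S_x = 0.5 * (S_x + S_x.T)
        S_e = 0.5 * (S_e_new + S_e_new.T)
    return L


def _estimator_pass(
    system: LinearSystem, costs: CostSchedule, L: np.ndarray, x0_hat: np.ndarray
):
    """Forward sweep: Kalman gains given control gains.

    ``Sig_xhat`` is the *uncentred* second moment of the state estimate:
    multiplicative noise is driven by the magnitude of the control signal,
    mean included, so the filter depends on the planned movement itself.
    """
    A, B, H = system.A, system.B, system.H
    c2 = system.c_scale**2
    Om_obs = system.obs_cov
    N = costs.horizon
    K = np.empty((N, N_STATES, N_OBS))
    Sig_e = np.zeros((N_STATES, N_STATES))  # estimate known exactly at t=0
    Sig_xhat = np.outer(x0_hat, x0_hat)
    Sig_xe = np.zeros((N_STATES, N_STATES))
    for t in range(N):
        Mio = H @ Sig_e @ H.T + Om_obs
        # ridge keeps the solve defined for noiseless channels (K -> 0)
        Mio[np.diag_indices_from(Mio)] += 1e-14 * (1.0 + np.trace(Mio))
        K[t] = np.linalg.solve(Mio.T, (A @ Sig_e @ H.T).T).T
        AKH = A - K[t] @ H
        ABL = A - B @ L[t]
        Sig_e_new = AKH @ Sig_e @ A.T
        if c2 > 0:
            Sig_e_new = Sig_e_new + c2 * np.trace(L[t] @ Sig_xhat @ L[t].T) * (B @ B.T)
        cross = ABL @ Sig_xe @ H.T @ K[t].T
        Sig_xhat_new = (
            K[t] @ H @ Sig_e @ A.T + ABL @ Sig_xhat @ ABL.T + cross + cross.T
        )
        Sig_xe = ABL @ Sig_xe @ AKH.T
        Sig_e = 0.5 * (Sig_e_new + Sig_e_new.T)
        Sig_xhat = 0.5 * (Sig_xhat_new + Sig_xhat_new.T)
    return K


def solve_finite_horizon(
    system: LinearSystem,
    costs: CostSchedule,
    x0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    use_kernel: bool = True,
) -> OptimalController:
    """Solve for the coupled optimal control and Kalman gain sequences.

    Parameters
    ----------
    system, costs
        Plant and cost schedule; dimensions must agree.
    x0
        Initial state (equal to the initial state estimate).  Only its outer
        product enters, through the control-dependent noise term of the
        filter; ``None`` means the zero state.
    tol, max_iter
        Convergence is declared when the largest absolute change of any gain
        element between successive sweeps falls below ``tol``.

    Returns
    -------
    OptimalController
        With ``converged=False`` (and the last gain delta) if the fixed point
        was not reached within ``max_iter`` sweeps.
    """
    if x0 is None:
        x0 = np.zeros(N_STATES)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (N_STATES,):
        raise ValueError("x0 must be an 8-vector")

    if use_kernel and _kernels.HAVE_NUMBA:
        L, K, it, delta, ok = _kernels.coupled_solve(
            system.A,
            system.B,
            system.H,
            float(system.c_scale**2),
            system.obs_cov,
            costs.Q,
            costs.R,
            x0,
            float(tol),
            int(max_iter),
        )
        return OptimalController(
            L=L, K=K, converged=bool(ok), iterations=int(it), gain_delta=float(delta)
        )

    N = costs.horizon
    K = np.zeros((N, N_STATES, N_OBS))
    L_prev = np.zeros((N, N_CONTROLS, N_STATES))
    delta = np.inf
    for it in range(1, max_iter + 1):
        L = _control_pass(system, costs, K)
        K_new = _estimator_pass(system, costs, L, x0)
        # gain change relative to gain magnitude, so the criterion does not
        # depend on the overall scale of the cost
        delta = max(
            np.max(np.abs(L - L_prev)) / max(1.0, np.max(np.abs(L))),
            np.max(np.abs(K_new - K)) / max(1.0, np.max(np.abs(K_new))),
        )
        K = K_new
        L_prev = L
        if delta < tol:
            return OptimalController(
                L=L, K=K, converged=True, iterations=it, gain_delta=float(delta)
            )
    return OptimalController(
        L=L_prev, K=K, converged=False, iterations=max_iter, gain_delta=float(delta)
    )


def _check_events(events, horizon):
    events = [] if events is None else list(events)
    for step, delta in events:
        if not 0 <= step <= horizon:
            raise ValueError(f"event step {step} outside horizon {horizon}")
        if np.shape(delta) != (N_STATES,):
            raise ValueError("event delta must be an 8-vector")
    return events


def simulate_mean_trajectory(
    system: LinearSystem,
    controller: OptimalController,
    x0: np.ndarray,
    events=None,
) -> Trajectory:
    """Deterministic rollout with every noise draw replaced by its mean.

    ``events`` is an optional list of ``(step, state_delta)`` pairs applied to
    both the true state and the estimate before the control at that step is
    computed -- used for commanded target jumps, which the participant sees
    directly (the target is not a sensory channel of the filter).

    The state estimate starts at ``x0`` and follows the Kalman recursion; with
    zero noise it tracks the true state exactly, so the rollout is seed-free
    and bit-stable.
    """
    A, B, H = system.A, system.B, system.H
    N = controller.horizon
    events = _check_events(events, N)
    x = np.asarray(x0, dtype=float).copy()
    xhat = x.copy()
    states = np.empty((N + 1, N_STATES))
    controls = np.empty((N, N_CONTROLS))
    for t in range(N):
        for step, delta in events:
            if step == t:
                x = x + delta
                xhat = xhat + delta
        states[t] = x
        u = -controller.L[t] @ xhat
        controls[t] = u
        x_next = A @ x + B @ u
        y = H @ x
        xhat = A @ xhat + B @ u + controller.K[t] @ (y - H @ xhat)
        x = x_next
    for step, delta in events:
        if step == N:
            x = x + delta
    states[N] = x
    times = np.arange(N + 1) * system.dt
    return Trajectory(states=states, controls=controls, times=times, dt=system.dt)


def simulate_noisy_trial(
    system: LinearSystem,
    controller: OptimalController,
    x0: np.ndarray,
    seed: int | np.random.Generator,
    events=None,
) -> Trajectory:
    """One stochastic rollout with multiplicative control noise and additive
    observation noise; reproducible given the seed."""
    rng = np.random.default_rng(seed)
    A, B, H = system.A, system.B, system.H
    N = controller.horizon
    events = _check_events(events, N)
    x = np.asarray(x0, dtype=float).copy()
    xhat = x.copy()
    states = np.empty((N + 1, N_STATES))
    controls = np.empty((N, N_CONTROLS))
    for t in range(N):
        for step, delta in events:
            if step == t:
                x = x + delta
                xhat = xhat + delta
        states[t] = x
        u = -controller.L[t] @ xhat
        controls[t] = u
        C = system.c_scale * rng.standard_normal((N_CONTROLS, N_CONTROLS))
        y = H @ x + system.d_scale * rng.standard_normal(N_OBS)
        x_next = A @ x + B @ ((np.eye(N_CONTROLS) + C) @ u)
        xhat = A @ xhat + B @ u + controller.K[t] @ (y - H @ xhat)
        x = x_next
    for step, delta in events:
        if step == N:
            x = x + delta
    states[N] = x
    times = np.arange(N + 1) * system.dt
    return Trajectory(states=states, controls=controls, times=times, dt=system.dt)


def realized_cost(traj: Trajectory, costs: CostSchedule) -> float:
    """Quadratic cost accumulated by a rollout under a cost schedule."""
    total = 0.0
    for t in range(costs.horizon + 1):
        x = traj.states[t]
        total += float(x @ costs.Q[t] @ x)
        if t < costs.horizon:
            u = traj.controls[t]
            total += float(costs.R[t] * (u @ u))
    return total
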