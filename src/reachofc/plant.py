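"""Linear plant for planar reaching with second-order muscle-like actuation.

The hand is a point mass moving in the horizontal plane, damped by intrinsic
muscle viscosity, and driven by two orthogonal force actuators.  Each actuator
is a first-order low-pass filter of the control signal (time constant ``tau``),
a standard stand-in for muscle activation dynamics.  The state vector stacks

    [px, py, vx, vy, fx, fy, tx, ty]

position, velocity, actuator force and target position, each in two Cartesian
dimensions.  Keeping the target inside the state lets a single quadratic cost
express "position error relative to the target" and lets a mid-movement target
jump be modelled as an instantaneous change of the state's target components.

Continuous dynamics per axis, discretized by forward Euler at step ``dt``:

    dp/dt = v
    dv/dt = (f - b * v) / m
    df/dt = (u - f) / tau

The control-dependent (signal-dependent) noise enters multiplicatively: the
applied control is ``(I + C) u`` where every element of the 2x2 matrix ``C``
is an independent zero-mean Gaussian with standard deviation ``c_scale``.
Observations are position, velocity and force (not the target), each corrupted
by additive Gaussian noise with per-channel standard deviations ``d_scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_STATES = 8
N_CONTROLS = 2
N_OBS = 6

# State component indices.
PX, PY, VX, VY, FX, FY, TX, TY = range(N_STATES)
POS = slice(0, 2)
VEL = slice(2, 4)
FRC = slice(4, 6)
TGT = slice(6, 8)

#: Default observation noise standard deviations for [px, py, vx, vy, fx, fy],
#: small relative to typical state magnitudes (m, m/s, N).
DEFAULT_D_SCALE = (1e-3, 1e-3, 1e-2, 1e-2, 5e-2, 5e-2)


@dataclass(frozen=True)
class PlantParams:
    """Physical and noise parameters of the reaching plant.

    Parameters
    ----------
    m : float
        Point mass of the hand, kg.
    b : float
        Intrinsic (muscle) viscosity, N*s/m.
    tau : float
        Muscle low-pass time constant, s.
    dt : float
        Simulation time step, s.
    c_scale : float
        Standard deviation of each element of the multiplicative
        control-noise matrix (dimensionless).
    d_scale : tuple of float
        Observation noise standard deviations for the six observed channels.
    """

    m: float = 1.1
    b: float = 7.0
    tau: float = 0.05
    dt: float = 0.01
    c_scale: float = 0.5
    d_scale: tuple[float, ...] = DEFAULT_D_SCALE

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError(f"mass must be positive, got {self.m}")
        if self.b < 0:
            raise ValueError(f"viscosity must be non-negative, got {self.b}")
        if self.tau <= 0:
            raise ValueError(f"muscle time constant must be positive, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"time step must be positive, got {self.dt}")
        if self.c_scale < 0:
            raise ValueError("c_scale must be non-negative")
        if len(self.d_scale) != N_OBS or any(d < 0 for d in self.d_scale):
            raise ValueError("d_scale must be 6 non-negative standard deviations")


@dataclass(frozen=True)
class LinearSystem:
    """Discrete-time system x' = A x + B (I + C) u, y = H x + noise."""

    A: np.ndarray
    B: np.ndarray
    H: np.ndarray
    c_scale: float
    d_scale: np.ndarray
    dt: float

    @property
    def obs_cov(self) -> np.ndarray:
        """Observation noise covariance (diagonal)."""
        return np.diag(self.d_scale**2)


def build_plant(params: PlantParams) -> LinearSystem:
    """Discretize the reaching dynamics into state-space matrices.

    Targets are stationary between commanded jumps, so their rows of ``A``
    are identity and they receive no control.  The observation matrix selects
    position, velocity and force only: the target is task knowledge, not a
    sensory channel.
    """
    dt, m, b, tau = params.dt, params.m, params.b, params.tau
    A = np.eye(N_STATES)
    A[PX, VX] = dt
    A[PY, VY] = dt
    A[VX, VX] = 1.0 - dt * b / m
    A[VY, VY] = 1.0 - dt * b / m
    A[VX, FX] = dt / m
    A[VY, FY] = dt / m
    A[FX, FX] = 1.0 - dt / tau
    A[FY, FY] = 1.0 - dt / tau

    B = np.zeros((N_STATES, N_CONTROLS))
    B[FX, 0] = dt / tau
    B[FY, 1] = dt / tau

    H = np.eye(N_STATES)[:N_OBS]

    return LinearSystem(
        A=A,
        B=B,
        H=H,
        c_scale=params.c_scale,
        d_scale=np.asarray(params.d_scale, dtype=float),
        dt=dt,
    )


def state_vector(
    position=(0.0, 0.0), velocity=(0.0, 0.0), force=(0.0, 0.0), target=(0.0, 0.0)
) -> np.ndarray:
    """Assemble an 8-component state from its four 2-vectors."""
    x = np.zeros(N_STATES)
    x[POS] = position
    x[VEL] = velocity
    x[FRC] = force
    x[TGT] = target
    if not np.all(np.isfinite(x)):
        raise ValueError("state components must be finite")
    return x


def reach_start_state(distance: float) -> np.ndarray:
    """Initial state of a forward reach: at rest at the origin, target
    ``distance`` metres straight ahead (+y)."""
    return state_vector(target=(0.0, distance))
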