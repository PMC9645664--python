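"""Linear biomechanical plant for planar reaching.

The hand is modelled as a planar point mass driven by a first-order
actuator (muscle-like low-pass on the commanded force).  Two external
forces act laterally: a constant background load ``phi`` (ramped up at
trial start) and a velocity-dependent force field ``Fx = theta * vy``
that is active only during the reach.

State vector (dimension 6)::

    x = [px, py, vx, vy, fx, fy]

with positions in metres, velocities in m/s and actuator forces in
newtons.  Continuous-time dynamics::

    d px/dt = vx                 d py/dt = vy
    d vx/dt = (fx + theta*vy + phi) / m
    d vy/dt = fy / m
    d fx/dt = (ux - fx) / tau    d fy/dt = (uy - fy) / tau

The discrete-time operators are the *exact* zero-order-hold
discretization of this system.  Because the force-field coupling
(vy -> vx) can never be traversed twice by any path through the state
graph, ``expm(A_c(theta) * dt)`` is exactly affine in ``theta``; the
plant therefore stores ``A(theta) = A0 + theta * dA`` (and likewise for
the control input operator), which also yields the exact parameter
sensitivity used by the adaptation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "NSTATE",
    "NCTRL",
    "PlantState",
    "LinearPlant",
    "ForceContext",
    "InvalidConfigError",
    "build_plant",
    "background_ramp",
    "external_force",
    "step",
]

NSTATE = 6
NCTRL = 2

# state indices
PX, PY, VX, VY, FX, FY = range(6)


class InvalidConfigError(ValueError):
    """Raised for physically meaningless plant configuration."""


@dataclass(frozen=True)
class PlantState:
    """Hand state: position (m), velocity (m/s), commanded force (N)."""

    px: float = 0.0
    py: float = 0.0
    vx: float = 0.0
    vy: float = 0.0
    fx: float = 0.0
    fy: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.px, self.py, self.vx, self.vy, self.fx, self.fy])

    @staticmethod
    def from_array(x: np.ndarray) -> "PlantState":
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite plant state")
        return PlantState(*(float(v) for v in np.asarray(x).reshape(NSTATE)))


@dataclass(frozen=True)
class ForceContext:
    """Per-trial force parameters.

    theta : force-field gain in N.s/m, clockwise positive (pushes the
        hand rightward, +x, for forward movement vy > 0).
    phi : signed lateral background load in N, rightward positive.
    ramp_duration : linear ramp-up time of the background load (s).
    """

    theta: float = 0.0
    phi: float = 0.0
    ramp_duration: float = 0.5

    def __post_init__(self):
        if self.ramp_duration < 0:
            raise InvalidConfigError("ramp_duration must be >= 0")


@dataclass(frozen=True)
class LinearPlant:
    """Exact discrete-time operators of the reaching plant.

    ``A(theta) = A0 + theta*dA`` and ``B(theta) = B0 + theta*dB`` are the
    zero-order-hold discretizations of the continuous system with the
    force field folded into the dynamics; ``E`` maps a constant lateral
    external force (N) held over one step into the next state.
    """

    dt: float
    mass: float
    actuator_tau: float
    A0: np.ndarray = field(repr=False)
    dA: np.ndarray = field(repr=False)
    B0: np.ndarray = field(repr=False)
    dB: np.ndarray = field(repr=False)
    E: np.ndarray = field(repr=False)
    H: np.ndarray = field(repr=False)
    process_noise: np.ndarray = field(repr=False)
    filter_process_noise: np.ndarray = field(repr=False)
    obs_noise: np.ndarray = field(repr=False)

    def A(self, theta: float = 0.0) -> np.ndarray:
        return self.A0 + theta * self.dA

    def B(self, theta: float = 0.0) -> np.ndarray:
        return self.B0 + theta * self.dB

    def with_noise(self, process_noise_scale: float, obs_noise_scale: float) -> "LinearPlant":
        W, Wf, V = _noise_covariances(process_noise_scale, obs_noise_scale)
        return replace(self, process_noise=W, filter_process_noise=Wf, obs_noise=V)


def _continuous_matrices(mass: float, actuator_tau: float, theta: float):
    """Continuous-time (A_c, B_c, E_c) with the field gain theta folded in."""
    A = np.zeros((NSTATE, NSTATE))
    A[PX, VX] = 1.0
    A[PY, VY] = 1.0
    A[VX, FX] = 1.0 / mass
    A[VX, VY] = theta / mass  # velocity-dependent force field
    A[VY, FY] = 1.0 / mass
    A[FX, FX] = -1.0 / actuator_tau
    A[FY, FY] = -1.0 / actuator_tau
    B = np.zeros((NSTATE, NCTRL))
    B[FX, 0] = 1.0 / actuator_tau
    B[FY, 1] = 1.0 / actuator_tau
    E = np.zeros((NSTATE, 1))
    E[VX, 0] = 1.0 / mass  # constant lateral load enters lateral acceleration
    return A, B, E


def _discretize(mass: float, actuator_tau: float, dt: float, theta: float):
    """Exact ZOH discretization via the augmented matrix exponential."""
    Ac, Bc, Ec = _continuous_matrices(mass, actuator_tau, theta)
    n_in = NCTRL + 1
    M = np.zeros((NSTATE + n_in, NSTATE + n_in))
    M[:NSTATE, :NSTATE] = Ac
    M[:NSTATE, NSTATE:NSTATE + NCTRL] = Bc
    M[:NSTATE, NSTATE + NCTRL:] = Ec
    Md = expm(M * dt)
    Ad = Md[:NSTATE, :NSTATE]
    Bd = Md[:NSTATE, NSTATE:NSTATE + NCTRL]
    Ed = Md[:NSTATE, NSTATE + NCTRL:]
    return Ad, Bd, Ed


# The Kalman filter's process-noise model carries a small floor on the
# position/velocity states (model-uncertainty term, standard practice) so
# that state errors caused by a misestimated field gain are observable and
# corrected by feedback; the *injected* motor noise acts on the actuator
# forces only.
_FILTER_POS_STD = 3e-3  # m
_FILTER_VEL_STD = 2e-2  # m/s


def _noise_covariances(process_noise_scale: float, obs_noise_scale: float):
    W = np.zeros((NSTATE, NSTATE))
    W[FX, FX] = W[FY, FY] = process_noise_scale ** 2
    Wf = W.copy()
    Wf[PX, PX] = Wf[PY, PY] = _FILTER_POS_STD ** 2
    Wf[VX, VX] = Wf[VY, VY] = _FILTER_VEL_STD ** 2
    V = np.eye(NSTATE) * max(obs_noise_scale, 1e-6) ** 2
    return W, Wf, V


def build_plant(
    dt: float = 0.01,
    mass: float = 1.0,
    actuator_tau: float = 0.1,
    process_noise_scale: float = 0.0,
    obs_noise_scale: float = 0.0,
) -> LinearPlant:
    """Build the discrete-time plant.

    Raises :class:`InvalidConfigError` for non-positive ``dt``, ``mass``
    or ``actuator_tau``.
    """
    if dt <= 0 or mass <= 0 or actuator_tau <= 0:
        raise InvalidConfigError(
            f"dt, mass and actuator_tau must be positive (got {dt}, {mass}, {actuator_tau})"
        )
    A0, B0, E0 = _discretize(mass, actuator_tau, dt, theta=0.0)
    A1, B1, _ = _discretize(mass, actuator_tau, dt, theta=1.0)
    W, Wf, V = _noise_covariances(process_noise_scale, obs_noise_scale)
    return LinearPlant(
        dt=dt,
        mass=mass,
        actuator_tau=actuator_tau,
        A0=A0,
        dA=A1 - A0,
        B0=B0,
        dB=B1 - B0,
        E=E0,
        H=np.eye(NSTATE),
        process_noise=W,
        filter_process_noise=Wf,
        obs_noise=V,
    )


def background_ramp(phi: float, t: float, ramp_duration: float = 0.5) -> float:
    """Background load at time ``t`` since trial start (linear ramp-up)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if ramp_duration <= 0:
        return phi
    return phi * min(t / ramp_duration, 1.0)


def external_force(
    state: PlantState, ctx: ForceContext, t: float, field_on: bool = True
) -> float:
    """Total lateral external force (N): background ramp plus, when the
    field is on, the velocity-dependent component ``theta * vy``.

    Catch trials are modelled by ``field_on=False`` (background only).
    """
    f = background_ramp(ctx.phi, t, ctx.ramp_duration)
    if field_on:
        f += ctx.theta * state.vy
    return f


def step(
    plant: LinearPlant,
    state: PlantState,
    command: np.ndarray,
    ctx: ForceContext,
    t: float = 0.0,
    field_on: bool = True,
    rng: np.random.Generator | None = None,
) -> PlantState:
    """Advance the plant one time step.

    The velocity-dependent field is integrated exactly (it is part of the
    discrete ``A`` operator); the background load is held at its value at
    the start of the step.  With ``rng=None`` or zero noise covariance the
    map is deterministic.
    """
    u = np.asarray(command, dtype=float).reshape(NCTRL)
    if not np.all(np.isfinite(u)):
        raise ValueError("command must be finite")
    theta = ctx.theta if field_on else 0.0
    bg = background_ramp(ctx.phi, t, ctx.ramp_duration)
    x = state.to_array()
    x_next = plant.A(theta) @ x + plant.B(theta) @ u + plant.E[:, 0] * bg
    if rng is not None and plant.process_noise[FX, FX] > 0:
        sd = np.sqrt(plant.process_noise[FX, FX])
        x_next[FX] += sd * rng.standard_normal()
        x_next[FY] += sd * rng.standard_normal()
    return PlantState.from_array(x_next)
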