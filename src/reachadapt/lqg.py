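"""Finite-horizon LQG control and Kalman estimation for reaching.

The controller is synthesized by the backward Riccati recursion for the
plant augmented with the *believed* force-field gain ``theta_hat``
(certainty equivalence).  Control acts on goal-referenced coordinates
``z = x - x_goal``; at the goal the actuator holds ``fx = -phi`` against
the background load, so the setpoint command compensates the background
exactly and the error dynamics are homogeneous.

Cost structure: a small running penalty on lateral position keeps the
reach straight (as human reaches are), and full position/velocity/force
penalties are applied from a "settle" step through the horizon, which
makes the movement complete within the movement time and then hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plant import NSTATE, NCTRL, LinearPlant, PlantState

__all__ = [
    "CostWeights",
    "ControllerGains",
    "EstimatorState",
    "NumericalFailureError",
    "goal_state",
    "stage_costs",
    "synthesize_controller",
    "riccati_gains",
    "control_command",
    "estimate_step",
]


class NumericalFailureError(RuntimeError):
    """Raised when a Riccati or filter iterate becomes non-finite/singular."""


@dataclass(frozen=True)
class CostWeights:
    """Quadratic cost weights for the reach controller.

    position, velocity, force: state penalties applied from
        ``settle_start`` (fraction of horizon) through the horizon.
    effort: command penalty ``r`` (> 0).
    lateral_position_run: running penalty on lateral position error
        during the movement phase (keeps the path straight).
    """

    position: float = 1e4
    velocity: float = 1e2
    force: float = 1e-2
    effort: float = 1e-4
    lateral_position_run: float = 1e2
    settle_fraction: float = 0.75

    def __post_init__(self):
        if self.effort <= 0:
            raise ValueError("effort weight must be > 0")
        if min(self.position, self.velocity, self.force, self.lateral_position_run) < 0:
            raise ValueError("state penalties must be >= 0")


@dataclass(frozen=True)
class ControllerGains:
    """Time-indexed feedback gains ``u_dev = -L[t] @ z``."""

    L: np.ndarray = field(repr=False)  # (horizon, NCTRL, NSTATE)
    horizon: int = 0
    theta_hat: float = 0.0


@dataclass
class EstimatorState:
    """Kalman filter state: estimate, error covariance, last gain."""

    x_hat: np.ndarray
    P: np.ndarray
    K: np.ndarray | None = None


def goal_state(phi: float = 0.0, reach_distance: float = 0.15):
    """Target state and setpoint command holding against the background.

    Returns ``(x_star, u_star)``: at rest on the goal the actuator must
    output ``fx = -phi`` so the net lateral force vanishes.
    """
    x_star = np.array([0.0, reach_distance, 0.0, 0.0, -phi, 0.0])
    u_star = np.array([-phi, 0.0])
    return x_star, u_star


def stage_costs(weights: CostWeights, horizon: int) -> np.ndarray:
    """State penalty matrices Q_t, t = 0..horizon (terminal included)."""
    settle_start = int(round(weights.settle_fraction * horizon))
    Q_run = np.zeros((NSTATE, NSTATE))
    Q_run[0, 0] = weights.lateral_position_run
    Q_hold = np.diag(
        [
            weights.position,
            weights.position,
            weights.velocity,
            weights.velocity,
            weights.force,
            weights.force,
        ]
    )
    Qs = np.empty((horizon + 1, NSTATE, NSTATE))
    for t in range(horizon + 1):
        Qs[t] = Q_hold if t >= settle_start else Q_run
    return Qs


def riccati_gains(A: np.ndarray, B: np.ndarray, Qs: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Backward Riccati recursion; returns gains L[t], t = 0..horizon-1.

    Generic in the state dimension (also used on scalar toy systems in
    tests).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n = A.shape[0]
    m = B.shape[1]
    horizon = Qs.shape[0] - 1
    L = np.empty((horizon, m, n))
    S = Qs[horizon].copy()
    for t in range(horizon - 1, -1, -1):
        SB = S @ B
        G = R + B.T @ SB
        try:
            L[t] = np.linalg.solve(G, SB.T @ A)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise NumericalFailureError("singular control Hessian in Riccati step") from exc
        S = Qs[t] + A.T @ S @ (A - B @ L[t])
        S = 0.5 * (S + S.T)
        if not np.all(np.isfinite(S)):
            raise NumericalFailureError("non-finite Riccati iterate")
    return L


def synthesize_controller(
    plant: LinearPlant,
    theta_hat: float,
    weights: CostWeights,
    horizon: int,
) -> ControllerGains:
    """LQR gains for the plant augmented with the believed field gain."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    Qs = stage_costs(weights, horizon)
    R = weights.effort * np.eye(NCTRL)
    L = riccati_gains(plant.A(theta_hat), plant.B(theta_hat), Qs, R)
    return ControllerGains(L=L, horizon=horizon, theta_hat=theta_hat)


def control_command(
    gains: ControllerGains,
    x_hat: np.ndarray | PlantState,
    t: int,
    x_star: np.ndarray | None = None,
    u_star: np.ndarray | None = None,
) -> np.ndarray:
    """Command at step ``t``: ``u = u_star - L[t] @ (x_hat - x_star)``."""
    if t >= gains.horizon:
        raise IndexError(f"step {t} outside horizon {gains.horizon}")
    if isinstance(x_hat, PlantState):
        x_hat = x_hat.to_array()
    z = np.asarray(x_hat, dtype=float)
    if x_star is not None:
        z = z - x_star
    u = -gains.L[t] @ z
    if u_star is not None:
        u = u + u_star
    return u


def estimate_step(
    plant: LinearPlant,
    theta_hat: float,
    est: EstimatorState,
    u: np.ndarray,
    y_meas: np.ndarray,
    known_lateral_force: float = 0.0,
):
    """One Kalman predict/update with the theta_hat-augmented dynamics.

    ``known_lateral_force`` is the deterministic background load fed
    through the disturbance channel.  Returns ``(EstimatorState,
    innovation)`` with ``innovation = y_meas - H @ x_hat_pred``.
    """
    A = plant.A(theta_hat)
    B = plant.B(theta_hat)
    H = plant.H
    x_pred = A @ est.x_hat + B @ np.asarray(u, dtype=float) + plant.E[:, 0] * known_lateral_force
    P_pred = A @ est.P @ A.T + plant.filter_process_noise
    innovation = np.asarray(y_meas, dtype=float) - H @ x_pred
    S = H @ P_pred @ H.T + plant.obs_noise
    # guard the noise-free limit: with V = 0 and P_pred = 0 the update is
    # pure prediction
    S_reg = S + 1e-15 * np.eye(S.shape[0])
    try:
        K = np.linalg.solve(S_reg.T, (P_pred @ H.T).T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalFailureError("singular innovation covariance") from exc
    x_new = x_pred + K @ innovation
    P_new = (np.eye(NSTATE) - K @ H) @ P_pred
    P_new = 0.5 * (P_new + P_new.T)
    return EstimatorState(x_hat=x_new, P=P_new, K=K), innovation
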