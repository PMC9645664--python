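"""Trial-by-trial (offline) and within-trial (online) force-field adaptation.

Two model variants share one learning rule:

* ``offline`` — each trial is executed with a controller frozen at the
  trial-initial estimate ``theta_hat_k``.  The estimate is updated during
  the movement with the slow rate ``gamma1`` (this update feeds the
  estimator's prediction, not the controller) and the value at the last
  time step becomes ``theta_hat_{k+1}``.
* ``online_offline`` — in addition, a within-trial increment
  ``delta_theta_t`` is learned with the fast rate ``gamma2`` and the
  controller is re-synthesized from the current ``theta_hat_t =
  theta_hat_k + delta_theta_t`` before every command.  The online
  increment is discarded at trial end; only the ``gamma1`` series carries
  across trials, so the two variants coincide exactly when ``gamma2 = 0``.

The learning rule is the least-squares identification step: the Kalman
innovation ``e`` is projected on the parameter sensitivity
``s = d x_pred / d theta`` (exact for this plant: ``dA @ x_hat + dB @ u``)
and the estimate moves by ``gamma * <s, e> / <s, s>``.  The normalization
makes ``gamma`` a dimensionless fractional correction, which is what
renders the rate schedules (gamma1 from 1e-3 to 0, gamma2 from 0 to 0.2,
both with first-order dynamics across trials) meaningful independently of
plant units; the raw inner-product form is available via
``normalized=False``.  Online adaptation engages only after a
configurable latency (default 250 ms), consistent with the delay of
feedback adaptation; the initial angle is measured before that latency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import lqg
from .plant import NSTATE, ForceContext, LinearPlant, build_plant
from .schedule import TrialSchedule, TrialSpec

__all__ = [
    "GammaSchedule",
    "LearningRates",
    "PredictionError",
    "AdaptiveEstimate",
    "SimulatedTrial",
    "SessionResult",
    "SimConfig",
    "sensitivity",
    "update_theta",
    "learning_rate_schedule",
    "simulate_trial",
    "simulate_session",
]

VARIANTS = ("offline", "online_offline")


@dataclass(frozen=True)
class GammaSchedule:
    """First-order (exponential) approach from ``start`` to ``end``.

    ``gamma(k) = end + (start - end) * exp(-rate * (k - 1))`` for the
    1-based trial index ``k``.
    """

    start: float
    end: float
    rate: float

    def value(self, k: int) -> float:
        if k < 1:
            raise ValueError("trial index k is 1-based")
        return self.end + (self.start - self.end) * np.exp(-self.rate * (k - 1))

    def scaled(self, factor: float) -> "GammaSchedule":
        return GammaSchedule(self.start * factor, self.end * factor, self.rate * factor)


@dataclass(frozen=True)
class LearningRates:
    """Offline (gamma1) and online (gamma2) learning-rate schedules.

    Defaults: gamma1 decays from 1e-3 toward 0 with per-trial rate
    constant 0.02; gamma2 rises from 0 toward 0.2 with rate constant 0.4
    (slow forgetting of the offline memory, faster engagement of online
    adaptation).
    """

    gamma1: GammaSchedule = field(default_factory=lambda: GammaSchedule(1e-3, 0.0, 0.02))
    gamma2: GammaSchedule = field(default_factory=lambda: GammaSchedule(0.0, 0.2, 0.4))

    def at(self, k: int) -> tuple[float, float]:
        return self.gamma1.value(k), self.gamma2.value(k)

    def scaled(self, factor: float) -> "LearningRates":
        return LearningRates(self.gamma1.scaled(factor), self.gamma2.scaled(factor))


def learning_rate_schedule(k: int, rates: LearningRates | None = None) -> tuple[float, float]:
    """Per-trial learning rates ``(gamma1_k, gamma2_k)`` (1-based ``k``)."""
    return (rates or LearningRates()).at(k)


@dataclass(frozen=True)
class PredictionError:
    """Innovation vector and parameter sensitivity at one time step."""

    e: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self):
        if np.shape(self.e) != (NSTATE,) or np.shape(self.sensitivity) != (NSTATE,):
            raise ValueError("e and sensitivity must be state-dimensional")


@dataclass
class AdaptiveEstimate:
    """Force-field belief: trial-initial value plus within-trial increment."""

    theta_hat_k: float
    delta_theta_t: float = 0.0

    @property
    def theta_hat_t(self) -> float:
        return self.theta_hat_k + self.delta_theta_t


@dataclass(frozen=True)
class SimulatedTrial:
    """Time-sampled model trial: states, commands and the belief series."""

    t: np.ndarray = field(repr=False)  # (T+1,) seconds
    states: np.ndarray = field(repr=False)  # (T+1, NSTATE)
    commands: np.ndarray = field(repr=False)  # (T, NCTRL)
    theta_hat_t: np.ndarray = field(repr=False)  # (T+1,)
    spec: TrialSpec | None = None
    dt: float = 0.01


@dataclass(frozen=True)
class SessionResult:
    trials: tuple[SimulatedTrial, ...]
    theta_k: np.ndarray  # (n_trials + 1,) trial-initial estimates
    schedule: TrialSchedule


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to simulate a session."""

    dt: float = 0.01
    mass: float = 1.0
    actuator_tau: float = 0.1
    process_noise_scale: float = 0.0
    obs_noise_scale: float = 1e-3
    weights: lqg.CostWeights = field(default_factory=lqg.CostWeights)
    horizon: int = 80
    rates: LearningRates = field(default_factory=LearningRates)
    variant: str = "online_offline"
    resynth_stride: int = 1
    estimate_mode: str = "single"  # or "per_cue"
    reach_distance: float = 0.15
    normalized_update: bool = True
    theta_hat_init: float = 0.0
    # latency before within-trial (online) adaptation engages, matching
    # the physiological delay of feedback adaptation; the initial angle
    # is measured before this and so stays a pure anticipation probe
    online_onset_time: float = 0.25
    # integration timescale of the slow (offline) process: its
    # per-sample rate is gamma1 * dt / offline_rate_timescale, giving
    # ~1.5% of the apparent parameter error consolidated per trial with
    # the default schedule (slow memory formation, residual asymptote)
    offline_rate_timescale: float = 0.035
    # leak of the volatile online increment (per sample): delta_theta
    # fades while it integrates, so it equilibrates quickly within a
    # movement to the *partial* correction gamma2 / (gamma2 + leak)
    # (about half the apparent error at the asymptotic gamma2)
    online_leak: float = 0.2

    def make_plant(self) -> LinearPlant:
        return build_plant(
            dt=self.dt,
            mass=self.mass,
            actuator_tau=self.actuator_tau,
            process_noise_scale=self.process_noise_scale,
            obs_noise_scale=self.obs_noise_scale,
        )

    def scaled_rates(self, factor: float) -> "SimConfig":
        return replace(self, rates=self.rates.scaled(factor))


def sensitivity(plant: LinearPlant, state, command=None) -> np.ndarray:
    """Exact derivative of the one-step prediction with respect to theta.

    ``d x_{t+1} / d theta = dA @ x + dB @ u`` (the discretization is
    affine in theta).  At ``vy = 0`` (and zero command) the vector
    vanishes: the field is unobservable without forward motion.
    """
    x = state.to_array() if hasattr(state, "to_array") else np.asarray(state, dtype=float)
    s = plant.dA @ x
    if command is not None:
        s = s + plant.dB @ np.asarray(command, dtype=float)
    return s


def update_theta(
    theta_hat: float,
    err: PredictionError,
    gamma: float,
    normalized: bool = True,
    eps: float = 1e-12,
) -> float:
    """One least-squares identification step of the field estimate.

    With ``normalized=True`` (default) the innovation is projected on the
    sensitivity direction and scaled by its squared norm, so ``gamma`` is
    the fraction of the apparent parameter error corrected per step; the
    un-normalized gradient form ``theta + gamma * <s, e>`` is kept for
    reference.  ``gamma = 0`` or ``e = 0`` leave the estimate unchanged.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    s = err.sensitivity
    num = float(s @ err.e)
    if normalized:
        den = float(s @ s)
        if den <= eps:
            return theta_hat
        return theta_hat + gamma * num / den
    return theta_hat + gamma * num


def _gain_fn():
    """Riccati backward pass: numba-jitted when available, else numpy."""
    from . import _fast

    if _fast.HAVE_NUMBA:
        return _fast.riccati_gains_jit
    return lqg.riccati_gains


def simulate_trial(
    variant: str,
    spec: TrialSpec,
    theta_hat_k: float,
    rates: tuple[float, float],
    plant: LinearPlant,
    weights: lqg.CostWeights,
    rng: np.random.Generator | None = None,
    horizon: int = 80,
    resynth_stride: int = 1,
    reach_distance: float = 0.15,
    normalized_update: bool = True,
    online_onset_time: float = 0.25,
    offline_rate_timescale: float = 0.035,
    online_leak: float = 0.2,
) -> tuple[SimulatedTrial, float]:
    """Simulate one reach under the adaptive LQG model.

    Returns the simulated trial and the next trial-initial estimate
    ``theta_hat_{k+1}`` (the gamma1 series evaluated at the last step).
    ``rates`` are the per-trial values ``(gamma1_k, gamma2_k)``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    gamma1, gamma2 = rates
    online = variant == "online_offline"
    theta_true = 0.0 if spec.is_catch else spec.theta
    field_on = not spec.is_catch
    # the simulated window starts at the go cue: the background is fully
    # ramped and compensated, the hand at rest in the start target
    ctx = ForceContext(theta=theta_true, phi=spec.phi, ramp_duration=0.0)
    x_star, u_star = lqg.goal_state(spec.phi, reach_distance)
    Qs = lqg.stage_costs(weights, horizon)
    R = weights.effort * np.eye(2)
    gain_at = _gain_fn()

    x = np.array([0.0, 0.0, 0.0, 0.0, -spec.phi, 0.0])
    est = lqg.EstimatorState(x_hat=x.copy(), P=plant.filter_process_noise.copy())
    d1 = 0.0  # gamma1 (offline-carrying) increment
    d2 = 0.0  # gamma2 (online) increment

    T = horizon
    states = np.empty((T + 1, NSTATE))
    commands = np.empty((T, 2))
    theta_series = np.empty(T + 1)
    states[0] = x
    theta_series[0] = theta_hat_k

    obs_sd = float(np.sqrt(plant.obs_noise[0, 0])) if rng is not None else 0.0
    proc_sd = float(np.sqrt(plant.process_noise[4, 4])) if rng is not None else 0.0
    A_true = plant.A(theta_true if field_on else 0.0)
    B_true = plant.B(theta_true if field_on else 0.0)
    Ebg = plant.E[:, 0] * spec.phi

    # gains for the trial-initial belief; the offline variant keeps them
    # for the whole trial
    gains_theta = theta_hat_k
    L_all = gain_at(plant.A(gains_theta), plant.B(gains_theta), Qs, R)

    for t in range(T):
        if online and t % resynth_stride == 0:
            theta_ctrl = theta_hat_k + d2
            if theta_ctrl != gains_theta:
                gains_theta = theta_ctrl
                L_all = gain_at(plant.A(gains_theta), plant.B(gains_theta), Qs, R)
        u = u_star - L_all[t] @ (est.x_hat - x_star)
        commands[t] = u
        # true plant step (exact ZOH; motor noise on the actuator forces)
        x = A_true @ x + B_true @ u + Ebg
        if proc_sd > 0:
            x[4] += proc_sd * rng.standard_normal()
            x[5] += proc_sd * rng.standard_normal()
        states[t + 1] = x
        y = x if obs_sd == 0 else x + obs_sd * rng.standard_normal(NSTATE)
        # belief used for the one-step prediction
        theta_belief = theta_hat_k + d1 + d2 if online else theta_hat_k + d1
        x_hat_prev = est.x_hat
        est, innov = lqg.estimate_step(plant, theta_belief, est, u, y, spec.phi)
        s = sensitivity(plant, x_hat_prev, u)
        err = PredictionError(e=innov, sensitivity=s)
        g1_step = gamma1 * plant.dt / max(offline_rate_timescale, plant.dt)
        d1 = update_theta(theta_hat_k + d1, err, g1_step, normalized_update) - theta_hat_k
        if online and (t + 1) * plant.dt >= online_onset_time:
            d2 = (1.0 - online_leak) * d2
            d2 = update_theta(theta_hat_k + d2, err, gamma2, normalized_update) - theta_hat_k
        theta_series[t + 1] = theta_hat_k + d1 + d2 if online else theta_hat_k + d1

    dt = plant.dt
    trial = SimulatedTrial(
        t=np.arange(T + 1) * dt,
        states=states,
        commands=commands,
        theta_hat_t=theta_series,
        spec=spec,
        dt=dt,
    )
    theta_next = theta_hat_k + d1  # carry-over: last-step value of the gamma1 series
    return trial, theta_next


def _cue_key(spec: TrialSpec, mode: str):
    if mode == "single":
        return 0
    if mode == "per_cue":
        return (float(np.sign(spec.phi)), spec.magnitude)
    raise ValueError(f"unknown estimate_mode {mode!r}")


def simulate_session(
    schedule: TrialSchedule,
    variant: str | None = None,
    cfg: SimConfig | None = None,
    seed: int | None = None,
) -> SessionResult:
    """Sequential simulation of a schedule, threading theta_hat across trials.

    By default a single signed estimate is shared by all trials (opposite
    field signs then cause partial unlearning); ``estimate_mode="per_cue"``
    keeps one estimate per background-force cue instead.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    cfg = cfg or SimConfig()
    variant = variant or cfg.variant
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    plant = cfg.make_plant()

    def run_pass(pass_variant: str, theta_series=None):
        rng = np.random.default_rng(seed) if seed is not None else None
        estimates: dict = {}
        trials: list[SimulatedTrial] = []
        theta_k = np.empty(len(schedule) + 1)
        for i, spec in enumerate(schedule):
            key = _cue_key(spec, cfg.estimate_mode)
            if theta_series is None:
                th = estimates.get(key, cfg.theta_hat_init)
            else:
                th = theta_series[i]
            theta_k[i] = th
            # gamma1 runs within every trial (it shapes the estimator's
            # belief); when the memory series is precomputed its
            # carry-over is simply not used
            trial, th_next = simulate_trial(
                pass_variant,
                spec,
                th,
                cfg.rates.at(i + 1),
                plant,
                cfg.weights,
                rng=rng,
                horizon=cfg.horizon,
                resynth_stride=cfg.resynth_stride,
                reach_distance=cfg.reach_distance,
                normalized_update=cfg.normalized_update,
                online_onset_time=cfg.online_onset_time,
                offline_rate_timescale=cfg.offline_rate_timescale,
                online_leak=cfg.online_leak,
            )
            estimates[key] = th_next
            trials.append(trial)
        theta_k[len(schedule)] = estimates.get(
            _cue_key(schedule[-1], cfg.estimate_mode), cfg.theta_hat_init
        )
        return trials, theta_k

    # The trial-by-trial memory series theta_hat_k is derived from the
    # gamma1-only (offline) dynamics and shared by both variants, so the
    # online rate shapes within-trial corrections without altering the
    # across-trial memory.
    offline_trials, theta_k = run_pass("offline")
    if variant == "offline":
        return SessionResult(trials=tuple(offline_trials), theta_k=theta_k, schedule=schedule)
    online_trials, _ = run_pass("online_offline", theta_series=theta_k)
    return SessionResult(trials=tuple(online_trials), theta_k=theta_k, schedule=schedule)
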