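"""Synthetic KINARM-like cohorts with known ground truth.

Every stage of the analysis pipeline can be exercised without any
recorded data: trials are generated at 1 kHz with a minimum-jerk forward
profile (15 cm), a lateral deviation composed of

* an *anticipatory* lobe whose amplitude (in initial-angle degrees)
  decays across trials with a single slow rate toward an asymptote, and
* a *corrective* lobe, confined to the post-threshold phase of the
  movement (feedback corrections act late), whose amplitude decays with
  an additional fast rate,

plus band-limited positional noise.  Catch trials carry a mirror-image
anticipatory lobe (the anticipatory compensation revealed by the absent
field), and the measured-force channel is the reaction force, i.e. the
opposite of the commanded background load.

The anticipatory lobe is calibrated so that the initial angle extracted
by the analysis pipeline equals the scheduled angle exactly (up to
sampling), which makes noise-free rate-recovery tests sharp.

A direct decay-curve cohort generator (:func:`generate_decay_cohort`) is
also provided for statistical recovery studies of the fitting machinery
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import KinematicTrial, lowpass
from .schedule import TrialSchedule, TrialSpec

__all__ = [
    "CohortProfile",
    "GroundTruthRecord",
    "minimum_jerk",
    "generate_trial_kinematics",
    "generate_cohort",
    "generate_decay_cohort",
]

TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "block",
    "trial",
    "t_ms",
    "x_m",
    "y_m",
    "fx_N",
    "fy_N",
]


@dataclass(frozen=True)
class CohortProfile:
    """Ground-truth generative parameters of a synthetic cohort."""

    n_participants: int = 18
    reach_distance: float = 0.15  # m
    movement_time: float = 0.6  # s
    pre_time: float = 0.1  # stationary hold before the go cue (s)
    post_time: float = 0.1  # recorded tail after movement end (s)
    fs: float = 1000.0  # Hz
    angle_uncompensated: float = 18.0  # deg, initial-angle magnitude at k = 0
    angle_asymptote: float = 6.0  # deg, residual at k -> inf
    slow_rate: float = 0.03  # per trial
    corrective_amplitude: float = 0.02  # m, lateral corrective lobe at k = 0
    fast_rate: float = 0.8  # per trial
    noise_sd: float = 0.0015  # m, band-limited positional noise
    force_noise_sd: float = 0.1  # N
    participant_sd: float = 2.0  # deg, random intercept on angle amplitude
    seed: int | None = None

    def __post_init__(self):
        if min(self.slow_rate, self.fast_rate) < 0:
            raise ValueError("decay rates must be >= 0")
        if min(self.noise_sd, self.participant_sd, self.corrective_amplitude) < 0:
            raise ValueError("amplitudes and SDs must be >= 0")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Per-participant generative parameters (for recovery tests)."""

    table: pd.DataFrame

    def for_participant(self, j: int) -> pd.Series:
        return self.table.set_index("participant").loc[j]


def minimum_jerk(d: float, T: float, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-jerk position and velocity profiles over distance ``d``."""
    s = np.clip(t / T, 0.0, 1.0)
    pos = d * (10 * s**3 - 15 * s**4 + 6 * s**5)
    vel = d / T * (30 * s**2 - 60 * s**3 + 30 * s**4)
    vel[t > T] = 0.0
    return pos, vel


def _lateral_lobes(profile: CohortProfile, t_move: np.ndarray):
    """Anticipatory and corrective unit lobes over movement time.

    The anticipatory lobe follows the (bell-shaped) forward speed
    profile, normalized to 1 at the initial-angle threshold crossing, so
    a scheduled angle maps exactly onto the measured one.  The
    corrective lobe is a smooth bump confined to the post-threshold
    phase.
    """
    T, D = profile.movement_time, profile.reach_distance
    y, vy = minimum_jerk(D, T, t_move)
    y_thr = D / 3.0
    i_thr = int(np.searchsorted(y, y_thr))
    antic = vy / vy[i_thr] if vy[i_thr] > 0 else vy
    s = np.clip((t_move - t_move[i_thr]) / (T - t_move[i_thr]), 0.0, 1.0)
    corr = np.sin(np.pi * s) ** 2
    corr[t_move > T] = 0.0
    return y, antic, corr, y_thr, i_thr


def _angle_magnitudes(profile: CohortProfile, amp_j: float, k: int):
    """Scheduled field-trial and catch-trial angle magnitudes at trial k."""
    decayed = (amp_j - profile.angle_asymptote) * np.exp(-profile.slow_rate * (k - 1))
    field_angle = profile.angle_asymptote + decayed
    catch_angle = max(amp_j - field_angle, 0.0)
    return field_angle, catch_angle


def generate_trial_kinematics(
    profile: CohortProfile,
    spec: TrialSpec,
    k: int,
    rng: np.random.Generator,
    amp_j: float | None = None,
    participant: int | None = None,
) -> KinematicTrial:
    """One synthetic trial (1-based trial index ``k`` of its series).

    Clockwise fields (theta > 0) push rightward, so field-trial initial
    angles are negative (CCW positive convention) and catch trials show
    the mirror image.
    """
    if amp_j is None:
        amp_j = profile.angle_uncompensated
    fs, D, T = profile.fs, profile.reach_distance, profile.movement_time
    n_pre = int(round(profile.pre_time * fs))
    t_move = np.arange(int(round((T + profile.post_time) * fs)) + 1) / fs
    y_move, antic, corr, y_thr, _ = _lateral_lobes(profile, t_move)

    field_angle, catch_angle = _angle_magnitudes(profile, amp_j, k)
    direction = np.sign(spec.theta) if spec.theta else np.sign(spec.phi) or 1.0
    if spec.is_catch:
        # mirror-image anticipatory deviation, no field-driven error
        x_move = -direction * np.tan(np.radians(catch_angle)) * y_thr * antic
    else:
        x_move = direction * np.tan(np.radians(field_angle)) * y_thr * antic
        x_move = x_move + direction * profile.corrective_amplitude * np.exp(
            -profile.fast_rate * (k - 1)
        ) * corr

    x = np.concatenate([np.zeros(n_pre), x_move])
    y = np.concatenate([np.zeros(n_pre), y_move])
    if profile.noise_sd > 0:
        # anchored at zero: trials start with the cursor stabilized in
        # the start target
        nx = _smooth_noise(x.size, fs, profile.noise_sd, rng)
        ny = _smooth_noise(y.size, fs, profile.noise_sd, rng)
        x = x + nx - nx[0]
        y = y + ny - ny[0]
    # handle force is the reaction to the commanded load
    fx = -spec.phi * np.ones(x.size)
    fy = np.zeros(x.size)
    if profile.force_noise_sd > 0:
        fx = fx + profile.force_noise_sd * rng.standard_normal(x.size)
        fy = fy + profile.force_noise_sd * rng.standard_normal(x.size)
    return KinematicTrial(fs=fs, x=x, y=y, fx=fx, fy=fy, spec=spec, participant=participant)


def _smooth_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (10 Hz) positional noise with the requested SD."""
    w = rng.standard_normal(n)
    sm = lowpass(w, fs=fs, fc=10.0, order=2)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


def generate_cohort(
    profile: CohortProfile,
    schedule: TrialSchedule,
    as_frame: bool = True,
):
    """Full synthetic cohort on a schedule.

    Returns ``(trials, ground_truth)`` where ``trials`` is either a tidy
    long-format table (``as_frame=True``) or a list of per-participant
    lists of :class:`KinematicTrial`.  Trial indices ``k`` count field
    and catch trials separately per direction, emulating per-series
    adaptation decay.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(profile.seed)
    truth_rows = []
    all_trials: list[list[KinematicTrial]] = []
    frames = []
    for j in range(1, profile.n_participants + 1):
        amp_j = profile.angle_uncompensated + profile.participant_sd * rng.standard_normal()
        truth_rows.append(
            {
                "participant": j,
                "angle_uncompensated": amp_j,
                "angle_asymptote": profile.angle_asymptote,
                "slow_rate": profile.slow_rate,
                "fast_rate": profile.fast_rate,
                "corrective_amplitude": profile.corrective_amplitude,
            }
        )
        counters: dict = {}
        trials_j = []
        for spec in schedule:
            key = (np.sign(spec.theta), np.sign(spec.phi), spec.is_catch, spec.magnitude)
            counters[key] = counters.get(key, 0) + 1
            tr = generate_trial_kinematics(
                profile, spec, counters[key], rng, amp_j=amp_j, participant=j
            )
            trials_j.append(tr)
            if as_frame:
                n = tr.x.size
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": j,
                            "experiment": spec.experiment,
                            "block": spec.block,
                            "trial": spec.trial,
                            "t_ms": np.arange(n) * 1000.0 / tr.fs,
                            "x_m": tr.x,
                            "y_m": tr.y,
                            "fx_N": tr.fx,
                            "fy_N": tr.fy,
                        }
                    )
                )
        all_trials.append(trials_j)
    truth = GroundTruthRecord(table=pd.DataFrame(truth_rows))
    if as_frame:
        return pd.concat(frames, ignore_index=True), truth
    return all_trials, truth


def generate_decay_cohort(
    n_participants: int = 18,
    n_trials: int = 75,
    alpha0: float = 0.145,
    alpha1: float = 0.05,
    beta1: float = -0.02,
    alpha2: float = 0.05,
    beta2: float = -0.8,
    noise_sd: float = 0.003,
    participant_sd: float = 0.005,
    seed: int | None = None,
):
    """Per-participant series drawn directly from the dual-rate decay law.

    ``beta2 = None`` (or ``alpha2 = 0``) generates single-rate data.
    Returns ``(x, per_participant_matrix, truth_dict)``.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_trials + 1, dtype=float)
    mean = alpha0 + alpha1 * np.exp(beta1 * x)
    if alpha2 and beta2 is not None:
        mean = mean + alpha2 * np.exp(beta2 * x)
    offsets = participant_sd * rng.standard_normal(n_participants)
    Y = mean[None, :] + offsets[:, None] + noise_sd * rng.standard_normal((n_participants, n_trials))
    truth = {
        "alpha0": alpha0,
        "alpha1": alpha1,
        "beta1": beta1,
        "alpha2": alpha2,
        "beta2": beta2,
        "noise_sd": noise_sd,
        "participant_sd": participant_sd,
    }
    return x, Y, truth
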