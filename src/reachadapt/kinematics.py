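"""Signal processing and trial metrics for reaching trajectories.

Pipeline order is fixed: zero-phase low-pass filtering of position and
force signals, numerical differentiation (4th-order centred stencil),
reach-onset detection (cursor exits the start target), then the two
kinematic metrics:

* **initial angle** (deg, CCW positive): angle between the +y axis and
  the segment from the start to the point where the path crosses a
  virtual threshold at one third of the reach distance; an anticipation
  probe, measured before feedback corrections act.
* **path length** (m): integral of hand speed from reach onset over a
  fixed 600 ms window; sensitive to anticipation *and* online
  corrections.

Measured-force convention: the handle force is the reaction to the
commanded load, so its sign is opposite to the commanded background
force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .schedule import TrialSpec

__all__ = [
    "KinematicTrial",
    "TrialMetrics",
    "NoOnsetError",
    "NoCrossingError",
    "lowpass",
    "differentiate",
    "reach_onset",
    "initial_angle",
    "path_length",
    "forward_velocity_at_threshold",
    "trial_metrics",
    "simulated_trial_metrics",
    "metrics_table",
    "pool_angles_across_directions",
]

DEFAULT_FS = 1000.0
DEFAULT_FC = 50.0
DEFAULT_ORDER = 4
DEFAULT_START_RADIUS = 0.005  # m; start-target radius for onset detection
DEFAULT_REACH = 0.15  # m
DEFAULT_WINDOW = 0.6  # s


class NoOnsetError(ValueError):
    """The cursor never exits the start target."""


class NoCrossingError(ValueError):
    """The path never crosses the initial-angle threshold."""


@dataclass(frozen=True)
class KinematicTrial:
    """One recorded (or synthesized) trial at a uniform sample rate."""

    fs: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    fx: np.ndarray = field(repr=False)
    fy: np.ndarray = field(repr=False)
    spec: TrialSpec | None = None
    participant: int | None = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sample rate must be > 0")
        n = len(self.x)
        if not (len(self.y) == len(self.fx) == len(self.fy) == n):
            raise ValueError("signal series must have equal lengths")


@dataclass(frozen=True)
class TrialMetrics:
    initial_angle: float  # deg, CCW positive
    path_length: float  # m
    onset_index: int
    threshold_crossing_time: float  # s from onset
    forward_velocity_at_threshold: float  # m/s


def lowpass(
    signal: np.ndarray,
    fs: float = DEFAULT_FS,
    fc: float = DEFAULT_FC,
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass.

    The dual pass squares the magnitude response of the ``order``-th
    order filter and cancels its phase.
    """
    if fc >= fs / 2:
        raise ValueError(f"cut-off {fc} Hz must be below the Nyquist frequency {fs / 2} Hz")
    b, a = butter(order, fc, fs=fs)
    # Gustafsson edge handling keeps the dual pass exactly symmetric
    # under time reversal
    return filtfilt(b, a, np.asarray(signal, dtype=float), method="gust")


# 4th-order finite-difference stencils (5 points): centred for the
# interior, one-sided at the edges
_CENTRAL = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0
_FORWARD = np.array([-25.0, 48.0, -36.0, 16.0, -3.0]) / 12.0


def differentiate(position: np.ndarray, fs: float = DEFAULT_FS) -> np.ndarray:
    """Velocity via the 5-point, 4th-order centred difference.

    Exact for polynomials up to degree 4 at interior points; the first
    and last two samples use one-sided 4th-order stencils.
    """
    p = np.asarray(position, dtype=float)
    if p.size < 5:
        raise ValueError("need at least 5 samples for the 4th-order stencil")
    v = np.convolve(p, _CENTRAL[::-1], mode="same")
    # edge fallback: one-sided 4th-order stencils
    for i in (0, 1):
        v[i] = _FORWARD @ p[i : i + 5]
        v[-1 - i] = -(_FORWARD @ p[-1 - i : -6 - i : -1])
    return v * fs


def reach_onset(trial: KinematicTrial, start_radius: float = DEFAULT_START_RADIUS) -> int:
    """First sample at which the cursor is outside the start target.

    The criterion is purely positional (distance from the first sample's
    position is irrelevant: the start target is at the origin).
    """
    d = np.hypot(trial.x, trial.y)
    if d[0] > start_radius:
        raise NoOnsetError("trial does not start inside the start target")
    outside = np.nonzero(d > start_radius)[0]
    if outside.size == 0:
        raise NoOnsetError("cursor never exits the start target")
    return int(outside[0])


def _threshold_crossing(trial: KinematicTrial, onset: int, y_thr: float):
    """Interpolated (x, index, fraction) where y first crosses ``y_thr``."""
    y = trial.y
    after = np.nonzero(y[onset:] >= y_thr)[0]
    if after.size == 0 or after[0] == 0:
        raise NoCrossingError(f"path never crosses y = {y_thr} m after onset")
    i = onset + after[0]
    f = (y_thr - y[i - 1]) / (y[i] - y[i - 1])
    x_c = trial.x[i - 1] + f * (trial.x[i] - trial.x[i - 1])
    return x_c, i, f


def initial_angle(
    trial: KinematicTrial,
    reach_distance: float = DEFAULT_REACH,
    start_radius: float = DEFAULT_START_RADIUS,
    onset: int | None = None,
) -> float:
    """Initial angle (deg) at the crossing of ``reach_distance / 3``.

    Positive angles are counter-clockwise rotations from straight ahead:
    a crossing left of the midline (x < 0) gives a positive angle.
    """
    if onset is None:
        onset = reach_onset(trial, start_radius)
    y_thr = reach_distance / 3.0
    x_c, _, _ = _threshold_crossing(trial, onset, y_thr)
    return float(np.degrees(np.arctan2(-x_c, y_thr)))


def path_length(
    trial: KinematicTrial,
    t_max: float = DEFAULT_WINDOW,
    start_radius: float = DEFAULT_START_RADIUS,
    onset: int | None = None,
    filter_cfg: dict | None = None,
    prefiltered: bool = False,
) -> float:
    """Integral of hand speed over the trace, truncated at
    ``onset + t_max`` (trapezoid).

    The hand is stationary before the reach, so the integral from the
    start of the trace is the arc length of the movement up to the
    truncation point.  Velocity is obtained by filtering then
    differentiating the position series; pass ``prefiltered=True`` for
    signals that need no filtering (e.g. noise-free model output).
    """
    if onset is None:
        onset = reach_onset(trial, start_radius)
    x, y = trial.x, trial.y
    if not prefiltered:
        cfg = filter_cfg or {}
        x = lowpass(x, trial.fs, **cfg)
        y = lowpass(y, trial.fs, **cfg)
    vx = differentiate(x, trial.fs)
    vy = differentiate(y, trial.fs)
    stop = min(len(x), onset + int(round(t_max * trial.fs)) + 1)
    speed = np.hypot(vx[:stop], vy[:stop])
    return float(np.trapezoid(speed, dx=1.0 / trial.fs))


def forward_velocity_at_threshold(
    trial: KinematicTrial,
    reach_distance: float = DEFAULT_REACH,
    start_radius: float = DEFAULT_START_RADIUS,
    onset: int | None = None,
    prefiltered: bool = False,
) -> float:
    """Forward velocity vy (m/s) at the initial-angle threshold crossing."""
    if onset is None:
        onset = reach_onset(trial, start_radius)
    y = trial.y if prefiltered else lowpass(trial.y, trial.fs)
    vy = differentiate(y, trial.fs)
    _, i, f = _threshold_crossing(trial, onset, reach_distance / 3.0)
    return float(vy[i - 1] + f * (vy[i] - vy[i - 1]))


def trial_metrics(
    trial: KinematicTrial,
    reach_distance: float = DEFAULT_REACH,
    start_radius: float = DEFAULT_START_RADIUS,
    t_max: float = DEFAULT_WINDOW,
    prefiltered: bool = False,
) -> TrialMetrics:
    """Full metric extraction: filter -> differentiate -> onset -> metrics."""
    if prefiltered:
        ft = trial
    else:
        ft = KinematicTrial(
            fs=trial.fs,
            x=lowpass(trial.x, trial.fs),
            y=lowpass(trial.y, trial.fs),
            fx=trial.fx,
            fy=trial.fy,
            spec=trial.spec,
            participant=trial.participant,
        )
    onset = reach_onset(ft, start_radius)
    ang = initial_angle(ft, reach_distance, onset=onset)
    pl = path_length(ft, t_max, onset=onset, prefiltered=True)
    _, i, f = _threshold_crossing(ft, onset, reach_distance / 3.0)
    vy_thr = forward_velocity_at_threshold(ft, reach_distance, onset=onset, prefiltered=True)
    t_cross = ((i - 1) + f - onset) / ft.fs
    return TrialMetrics(
        initial_angle=ang,
        path_length=pl,
        onset_index=onset,
        threshold_crossing_time=float(t_cross),
        forward_velocity_at_threshold=vy_thr,
    )


def simulated_trial_metrics(sim, **kwargs) -> TrialMetrics:
    """Metrics for a model :class:`~reachadapt.adaptation.SimulatedTrial`.

    Model output is noise-free in the measurement sense and sampled at
    1/dt, so no low-pass filtering is applied.
    """
    trial = KinematicTrial(
        fs=1.0 / sim.dt,
        x=sim.states[:, 0],
        y=sim.states[:, 1],
        fx=-np.full(len(sim.t), sim.spec.phi if sim.spec else 0.0),
        fy=np.zeros(len(sim.t)),
        spec=sim.spec,
    )
    return trial_metrics(trial, prefiltered=True, **kwargs)


def metrics_table(trials, participants=None, **kwargs) -> pd.DataFrame:
    """Metrics for a sequence of trials as a tidy table."""
    rows = []
    for j, tr in enumerate(trials):
        m = (
            simulated_trial_metrics(tr, **kwargs)
            if hasattr(tr, "states")
            else trial_metrics(tr, **kwargs)
        )
        spec = tr.spec
        rows.append(
            {
                "participant": participants[j]
                if participants is not None
                else getattr(tr, "participant", None),
                "trial": spec.trial if spec else j + 1,
                "is_catch": spec.is_catch if spec else False,
                "theta_Nspm": spec.theta if spec else np.nan,
                "phi_N": spec.phi if spec else np.nan,
                "initial_angle_deg": m.initial_angle,
                "path_length_m": m.path_length,
                "vy_at_threshold": m.forward_velocity_at_threshold,
            }
        )
    return pd.DataFrame(rows)


def pool_angles_across_directions(angles: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Map both field directions onto a positive decay before averaging.

    The direction whose mean early angle is negative is negated, so that
    clockwise and counter-clockwise series can be pooled.  ``groups``
    labels the direction of each series row.
    """
    a = np.array(angles, dtype=float)
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        n_early = max(1, min(5, sel.sum()))
        if np.nanmean(a[sel][:n_early]) < 0:
            a[sel] = -a[sel]
    return a
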