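"""Trial schedules for the three background-force-cue experiments.

Experiment 1: clockwise/counter-clockwise force fields (|theta| = 13
N.s/m) cued by leftward/rightward background loads (|phi| = 4 N), in a
positive (theta*phi > 0) and a negative context, with random catch
trials, a washout block, and a final no-background control block.

Experiment 2: light vs heavy rightward cues (phi = 2.5/5 N) with
proportional fields (theta = 7.5/15 N.s/m), randomly interleaved.

Experiment 3: one heavy-only block, then two blocks identical to
Experiment 2.

"Randomly interleaved" is implemented as a uniform permutation of each
block's trial multiset; composition counts are seed-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialSpec",
    "TrialSchedule",
    "experiment1_schedule",
    "experiment2_schedule",
    "experiment3_schedule",
    "constant_field_session",
    "write_schedule",
    "read_schedule",
]

PHI_EXP1 = 4.0
THETA_EXP1 = 13.0
PHI_LIGHT, PHI_HEAVY = 2.5, 5.0
THETA_LIGHT, THETA_HEAVY = 7.5, 15.0

SCHEDULE_COLUMNS = [
    "experiment",
    "block",
    "trial",
    "context",
    "phi_N",
    "theta_Nspm",
    "is_catch",
    "magnitude",
]


@dataclass(frozen=True)
class TrialSpec:
    """One trial of an experimental session.

    ``context`` is +1/-1 for the positive/negative cue-field association
    (0 when not applicable), ``magnitude`` is ``"light"``/``"heavy"``
    for Experiments 2-3 (empty otherwise).
    """

    experiment: int
    block: int
    trial: int  # 1-based index within the session
    context: int
    phi: float
    theta: float
    is_catch: bool
    magnitude: str = ""

    def __post_init__(self):
        if self.is_catch and self.theta != 0.0:
            raise ValueError("catch trials have no force field (theta must be 0)")
        if self.theta != 0.0 and self.phi != 0.0 and self.context != 0:
            if self.context != int(np.sign(self.theta * self.phi)):
                raise ValueError("context sign must equal sign(theta*phi)")


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[TrialSpec, ...]
    experiment: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[TrialSpec]:
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def blocks(self) -> dict[int, list[TrialSpec]]:
        out: dict[int, list[TrialSpec]] = {}
        for tr in self.trials:
            out.setdefault(tr.block, []).append(tr)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "experiment": tr.experiment,
                "block": tr.block,
                "trial": tr.trial,
                "context": tr.context,
                "phi_N": tr.phi,
                "theta_Nspm": tr.theta,
                "is_catch": tr.is_catch,
                "magnitude": tr.magnitude,
            }
            for tr in self.trials
        ]
        return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def _renumber(trials: Sequence[TrialSpec]) -> tuple[TrialSpec, ...]:
    return tuple(replace(tr, trial=i + 1) for i, tr in enumerate(trials))


def _permuted(block: list[TrialSpec], rng: np.random.Generator) -> list[TrialSpec]:
    order = rng.permutation(len(block))
    return [block[i] for i in order]


def _exp1_block(block: int, context: int, rng: np.random.Generator) -> list[TrialSpec]:
    trials: list[TrialSpec] = []
    for phi_sign in (+1, -1):
        phi = phi_sign * PHI_EXP1
        theta = context * phi_sign * THETA_EXP1
        trials += [
            TrialSpec(1, block, 0, context, phi, theta, False) for _ in range(25)
        ]
        trials += [TrialSpec(1, block, 0, context, phi, 0.0, True) for _ in range(5)]
    return _permuted(trials, rng)


def experiment1_schedule(
    order: str = "positive_first", seed: int | None = None
) -> TrialSchedule:
    """Full Experiment-1 session.

    Blocks 1-3: first context (3 x 60 trials: 50 field, 25 per background
    direction; 10 catch, 5 per direction).  Block 4: washout (30 trials,
    background only, 15 per direction).  Blocks 5-7: opposite context.
    Block 8: control, 30 field trials (15 per direction) without
    background force.
    """
    if order == "positive_first":
        contexts = (+1, -1)
    elif order == "negative_first":
        contexts = (-1, +1)
    else:
        raise ValueError(f"unknown order {order!r}; use positive_first|negative_first")
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for b in (1, 2, 3):
        trials += _exp1_block(b, contexts[0], rng)
    washout = [
        TrialSpec(1, 4, 0, 0, s * PHI_EXP1, 0.0, True)
        for s in (+1, -1)
        for _ in range(15)
    ]
    trials += _permuted(washout, rng)
    for b in (5, 6, 7):
        trials += _exp1_block(b, contexts[1], rng)
    control = [
        TrialSpec(1, 8, 0, 0, 0.0, s * THETA_EXP1, False)
        for s in (+1, -1)
        for _ in range(15)
    ]
    trials += _permuted(control, rng)
    return TrialSchedule(_renumber(trials), experiment=1, seed=seed)


def _magnitude_block(experiment: int, block: int, rng: np.random.Generator) -> list[TrialSpec]:
    trials: list[TrialSpec] = []
    for label, phi, theta in (
        ("light", PHI_LIGHT, THETA_LIGHT),
        ("heavy", PHI_HEAVY, THETA_HEAVY),
    ):
        trials += [
            TrialSpec(experiment, block, 0, +1, phi, theta, False, label)
            for _ in range(25)
        ]
        trials += [
            TrialSpec(experiment, block, 0, 0, phi, 0.0, True, label)
            for _ in range(5)
        ]
    return _permuted(trials, rng)


def experiment2_schedule(seed: int | None = None) -> TrialSchedule:
    """Six 60-trial blocks of interleaved light/heavy field and catch trials."""
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    for b in range(1, 7):
        trials += _magnitude_block(2, b, rng)
    return TrialSchedule(_renumber(trials), experiment=2, seed=seed)


def experiment3_schedule(seed: int | None = None) -> TrialSchedule:
    """Heavy-only first block (50 field + 10 catch), then two Experiment-2 blocks."""
    rng = np.random.default_rng(seed)
    first: list[TrialSpec] = [
        TrialSpec(3, 1, 0, +1, PHI_HEAVY, THETA_HEAVY, False, "heavy") for _ in range(50)
    ] + [TrialSpec(3, 1, 0, 0, PHI_HEAVY, 0.0, True, "heavy") for _ in range(10)]
    trials = _permuted(first, rng)
    for b in (2, 3):
        trials += _magnitude_block(3, b, rng)
    return TrialSchedule(_renumber(trials), experiment=3, seed=seed)


def constant_field_session(
    n_trials: int = 75,
    theta: float = THETA_EXP1,
    phi: float = PHI_EXP1,
) -> TrialSchedule:
    """A single-direction field-trial series (the per-direction series of
    one context, used for model simulations of the adaptation time
    course)."""
    context = int(np.sign(theta * phi)) if theta and phi else 0
    trials = tuple(
        TrialSpec(0, 1, k + 1, context, phi, theta, False) for k in range(n_trials)
    )
    return TrialSchedule(trials, experiment=0, seed=None)


def write_schedule(schedule: TrialSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path) -> TrialSchedule:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule file missing columns: {missing}")
    trials = tuple(
        TrialSpec(
            experiment=int(r.experiment),
            block=int(r.block),
            trial=int(r.trial),
            context=int(r.context),
            phi=float(r.phi_N),
            theta=float(r.theta_Nspm),
            is_catch=bool(r.is_catch),
            magnitude=str(r.magnitude),
        )
        for r in df.itertuples()
    )
    return TrialSchedule(trials, experiment=int(df["experiment"].iloc[0]) if len(df) else 0)
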