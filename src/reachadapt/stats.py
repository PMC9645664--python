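"""Paired comparisons, effect size, analytic power, and mixed models.

The power of a paired comparison is computed with the normal
approximation

    power = 1 - Phi(T - d_bar / (sigma / sqrt(n)))

where ``d_bar`` and ``sigma`` are the mean and SD of the per-participant
differences and ``T`` is the ``1 - alpha`` standard-normal quantile
(default ``alpha = 0.005``).  Effect sizes are the mean difference
divided by the SD of the pooled data — note this pooled SD is *not* the
SD of differences entering the power formula, so power cannot be
recovered from the effect size alone.

Mixed linear models ``Y_ij = X b + s_j + e_ij`` with a participant
random intercept are fitted by REML (ML optional) through statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "PairedComparison",
    "MixedModelSpec",
    "MixedModelFit",
    "DegenerateTestError",
    "paired_t",
    "effect_size_pooled",
    "power_eq1",
    "epoch_average",
    "fit_random_intercept_lmm",
]


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance)."""


@dataclass(frozen=True)
class PairedComparison:
    d: np.ndarray = field(repr=False)
    d_bar: float = 0.0
    sigma: float = 0.0
    n: int = 0
    t: float = np.nan
    df: int = 0
    p: float = np.nan
    sidedness: str = "two-sided"
    alpha: float = 0.005


@dataclass(frozen=True)
class MixedModelSpec:
    """Formula-style specification of a random-intercept model."""

    response: str
    fixed: str  # patsy right-hand side, e.g. "magnitude * trial"
    group: str = "participant"
    reml: bool = True


@dataclass(frozen=True)
class MixedModelFit:
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    converged: bool
    method: str


def paired_t(d: np.ndarray, sidedness: str = "two-sided", alpha: float = 0.005) -> PairedComparison:
    """Classical paired t-test on a vector of per-participant differences.

    ``sidedness`` is explicit: "two-sided", "greater" (d_bar > 0) or
    "less".
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sigma = float(d.std(ddof=1))
    if sigma == 0:
        raise DegenerateTestError("zero variance of differences")
    d_bar = float(d.mean())
    t = d_bar / (sigma / np.sqrt(n))
    df = n - 1
    if sidedness == "two-sided":
        p = 2 * sps.t.sf(abs(t), df)
    elif sidedness == "greater":
        p = sps.t.sf(t, df)
    elif sidedness == "less":
        p = sps.t.cdf(t, df)
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    return PairedComparison(
        d=d, d_bar=d_bar, sigma=sigma, n=n, t=float(t), df=df, p=float(p),
        sidedness=sidedness, alpha=alpha,
    )


def effect_size_pooled(cond_a: np.ndarray, cond_b: np.ndarray) -> float:
    """Mean difference divided by the SD of the pooled data."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("conditions must have equal lengths")
    pooled_sd = float(np.concatenate([a, b]).std(ddof=1))
    if pooled_sd == 0:
        raise DegenerateTestError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled_sd)


def power_eq1(d_bar: float, sigma: float, n: int, alpha: float = 0.005) -> float:
    """Normal-approximation power of a one-sided paired comparison.

    ``1 - Phi(T - d_bar/(sigma/sqrt(n)))`` with ``T`` the ``1 - alpha``
    standard-normal quantile.  At ``d_bar = 0`` the power equals
    ``alpha``; it is increasing in ``n`` and in ``d_bar/sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    T = sps.norm.ppf(1 - alpha)
    return float(1 - sps.norm.cdf(T - d_bar / (sigma / np.sqrt(n))))


def epoch_average(series: np.ndarray, window) -> float:
    """Mean of a named or sliced epoch of a trial series.

    ``window`` is ``("last", m)``, ``("first", m)`` or a ``slice``.
    """
    y = np.asarray(series, dtype=float)
    if isinstance(window, slice):
        sel = y[window]
    else:
        kind, m = window
        if m > y.size:
            raise ValueError(f"window of {m} exceeds series length {y.size}")
        sel = y[-m:] if kind == "last" else y[:m]
    if sel.size == 0:
        raise ValueError("empty epoch")
    return float(sel.mean())


def fit_random_intercept_lmm(table: pd.DataFrame, spec: MixedModelSpec) -> MixedModelFit:
    """REML (default) fit of ``Y = X b + s_j + e`` with participant
    random intercepts.

    The two designs used for the magnitude experiments are expressed as
    formulas, e.g. ``"magnitude * trial"`` (intercept, magnitude,
    trial index, interaction) and ``"magnitude * experiment"``.
    t-statistics use the residual (n_obs-based) normal approximation
    reported by statsmodels.
    """
    for col in [spec.response, spec.group]:
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    if table[spec.group].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    model = smf.mixedlm(
        f"{spec.response} ~ {spec.fixed}", data=table, groups=table[spec.group]
    )
    try:
        res = model.fit(reml=spec.reml)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient or ill-conditioned design") from exc
    fe = res.fe_params.index
    return MixedModelFit(
        params=res.params[fe],
        tvalues=res.tvalues[fe],
        pvalues=res.pvalues[fe],
        group_var=float(np.asarray(res.cov_re)[0, 0]),
        resid_var=float(res.scale),
        n_obs=int(res.nobs),
        n_groups=table[spec.group].nunique(),
        converged=bool(res.converged),
        method="reml" if spec.reml else "ml",
    )
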