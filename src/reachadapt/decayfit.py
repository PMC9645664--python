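"""Single- and dual-rate exponential decay models of trial series.

Models (trial index ``x``, metric ``y``)::

    single:  f(x) = a0 + a1 * exp(b1 * x)
    dual:    f(x) = a0 + a1 * exp(b1 * x) + a2 * exp(b2 * x)

with the reporting convention that decay rates ``b`` are *negative*
(internally the fits use ``exp(-lambda x)`` with ``lambda >= 0``).  The
maximum-likelihood estimate under i.i.d. Gaussian residuals is the
nonlinear least-squares fit; it is computed by variable projection
(for fixed rates the amplitudes are a linear subproblem), multi-start
over a rate grid, and a final polish of the rate parameters.  Model
selection uses the BIC approximation

    BIC = N * ln(RSS / N) + k * ln(N),      k = 3 (single) or 5 (dual)

and the smaller-BIC model wins (ties go to the single-rate model).
Parameter uncertainty comes from the Gaussian approximation (Wald
intervals from the inverse observed information, i.e. the standard NLS
covariance) and from a participant bootstrap: resample participants
with replacement, average, refit; non-converging iterations are
discarded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecaySeries",
    "DecayFit",
    "BootstrapResult",
    "FitError",
    "fit_single_rate",
    "fit_dual_rate",
    "bic",
    "select_model",
    "parameter_ci",
    "bootstrap_decay",
]

# multi-start rate grids (per-trial units)
FAST_GRID = (0.2, 0.5, 1.0, 2.0)
SLOW_GRID = (0.005, 0.02, 0.05)
SINGLE_GRID = tuple(sorted(set(SLOW_GRID + FAST_GRID + (0.1,))))

_RSS_FLOOR = 1e-300  # guards ln(RSS) for (near-)perfect fits


class FitError(RuntimeError):
    """Raised when no usable fit can be produced at all."""


@dataclass(frozen=True)
class DecaySeries:
    """A metric series over trials, optionally with per-participant rows.

    ``y`` is the series the models are fitted to (typically the
    participant average); ``per_participant`` (P x N) enables the
    bootstrap.
    """

    x: np.ndarray
    y: np.ndarray
    per_participant: np.ndarray | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.per_participant is not None:
            pp = np.asarray(self.per_participant, dtype=float)
            object.__setattr__(self, "per_participant", pp)
            if pp.ndim != 2 or pp.shape[1] != x.size:
                raise ValueError("per_participant must be (P, len(x))")

    @staticmethod
    def from_cohort(x, per_participant) -> "DecaySeries":
        pp = np.asarray(per_participant, dtype=float)
        return DecaySeries(x=np.asarray(x, dtype=float), y=pp.mean(axis=0), per_participant=pp)


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential decay model.

    Rates follow the reporting convention (negative = decay); for the
    dual model ``beta1`` is the slow and ``beta2`` the fast rate
    (|beta2| > |beta1|).
    """

    model: str  # "single" | "dual"
    alpha0: float
    alpha1: float
    beta1: float
    alpha2: float | None = None
    beta2: float | None = None
    residuals: np.ndarray = field(default=None, repr=False)
    n_obs: int = 0
    k_params: int = 0
    rss: float = np.nan
    cov: np.ndarray = field(default=None, repr=False)
    converged: bool = False

    @property
    def params(self) -> np.ndarray:
        if self.model == "single":
            return np.array([self.alpha0, self.alpha1, self.beta1])
        return np.array([self.alpha0, self.alpha1, self.beta1, self.alpha2, self.beta2])

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.model == "single":
            return ("alpha0", "alpha1", "beta1")
        return ("alpha0", "alpha1", "beta1", "alpha2", "beta2")

    @property
    def bic(self) -> float:
        return bic(self)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.alpha0 + self.alpha1 * np.exp(self.beta1 * x)
        if self.model == "dual":
            out = out + self.alpha2 * np.exp(self.beta2 * x)
        return out


@dataclass(frozen=True)
class BootstrapResult:
    """Participant-resampling bootstrap of decay parameters."""

    draws: np.ndarray = field(repr=False)  # (n_retained, k)
    param_names: tuple[str, ...]
    n_requested: int
    n_retained: int
    ci: dict
    level: float
    seed: int | None

    @property
    def discarded_fraction(self) -> float:
        return 1.0 - self.n_retained / self.n_requested


def _linear_amplitudes(x, y, lams):
    """Profile out the amplitudes for fixed decay rates."""
    cols = [np.ones_like(x)] + [np.exp(-lam * x) for lam in lams]
    M = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
    r = y - M @ coef
    return coef, float(r @ r)


def _polish(x, y, lams0, bounds_hi=3.0):
    """Refine the rates by NLS with profiled amplitudes.

    Rates are bounded at 3 per unit x: at unit spacing a component
    decaying faster than e^{-3} per step is within 5% of a single-point
    impulse and cannot be identified.
    """

    def resid(lams):
        cols = [np.ones_like(x)] + [np.exp(-lam * x) for lam in lams]
        M = np.column_stack(cols)
        coef, _, _, _ = np.linalg.lstsq(M, y, rcond=None)
        return y - M @ coef

    sol = optimize.least_squares(
        resid,
        np.asarray(lams0, dtype=float),
        bounds=(0.0, bounds_hi),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    coef, rss = _linear_amplitudes(x, y, sol.x)
    return sol, coef, rss


def _full_covariance(x, y, coef, lams, rss):
    """NLS covariance of the full parameter vector (amplitudes + rates).

    Built from the Jacobian of the model in the *reported*
    parameterization (rates beta = -lambda); note d f / d beta =
    x * a * exp(beta x) so the sign change leaves the covariance of the
    rates unchanged.
    """
    n = x.size
    k = 1 + 2 * len(lams)
    if n <= k:
        return None
    cols = [np.ones_like(x)]
    for a, lam in zip(coef[1:], lams):
        cols.append(np.exp(-lam * x))
    for a, lam in zip(coef[1:], lams):
        cols.append(a * x * np.exp(-lam * x))  # w.r.t. beta = -lambda
    J = np.column_stack(cols)
    sigma2 = rss / (n - k)
    JtJ = J.T @ J
    try:
        cov = sigma2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        return None
    # reorder to (a0, a1, b1[, a2, b2])
    if len(lams) == 1:
        order = [0, 1, 2]
    else:
        order = [0, 1, 3, 2, 4]
    return cov[np.ix_(order, order)]


def fit_single_rate(series: DecaySeries, init=None) -> DecayFit:
    """MLE of the single-rate model ``a0 + a1 exp(b1 x)``."""
    x, y = series.x, series.y
    if x.size < 4:
        raise ValueError("single-rate fit needs at least 4 points")
    grid = list(SINGLE_GRID)
    if init is not None:
        grid.insert(0, abs(float(np.asarray(init)[2])))
    scored = sorted(grid, key=lambda lam: _linear_amplitudes(x, y, [lam])[1])
    # polish the few best grid starts: the profiled objective can have
    # multiple basins (a warm start narrows the search)
    sol = coef = rss = None
    for lam0 in scored[: 2 if init is not None else 3]:
        s, c, r = _polish(x, y, [lam0])
        if rss is None or (s.success and not sol.success) or (
            r < rss and (s.success or not sol.success)
        ):
            sol, coef, rss = s, c, r
    lam = float(sol.x[0])
    cov = _full_covariance(x, y, coef, [lam], rss)
    residuals = y - (coef[0] + coef[1] * np.exp(-lam * x))
    return DecayFit(
        model="single",
        alpha0=float(coef[0]),
        alpha1=float(coef[1]),
        beta1=-lam,
        residuals=residuals,
        n_obs=x.size,
        k_params=3,
        rss=rss,
        cov=cov,
        converged=bool(sol.success and np.isfinite(rss)),
    )


def fit_dual_rate(series: DecaySeries, init=None) -> DecayFit:
    """MLE of the dual-rate model; output ordered slow (b1), fast (b2).

    Dual-exponential least squares is multimodal, so the rate pair is
    multi-started on a fast x slow grid before polishing; a degenerate
    second component (a2 ~ 0 or b2 ~ b1) is returned as-is and left to
    the BIC to reject.
    """
    x, y = series.x, series.y
    if x.size < 6:
        raise ValueError("dual-rate fit needs at least 6 points")
    pairs = [(f, s) for f in FAST_GRID for s in SLOW_GRID]
    if init is not None:
        b1, b2 = float(init[2]), float(init[4])
        pairs.insert(0, (abs(b2), abs(b1)))
    scored = sorted(pairs, key=lambda p: _linear_amplitudes(x, y, list(p))[1])
    sol = coef = rss = None
    for pair in scored[: 2 if init is not None else 3]:
        s, c, r = _polish(x, y, list(pair))
        if rss is None or (s.success and not sol.success) or (
            r < rss and (s.success or not sol.success)
        ):
            sol, coef, rss = s, c, r
    lams = [float(v) for v in sol.x]
    # order components slow first (reported b1 = slow, b2 = fast)
    comps = sorted(zip(lams, coef[1:]), key=lambda p: p[0])
    (lam_slow, a_slow), (lam_fast, a_fast) = comps
    cov = _full_covariance(x, y, np.array([coef[0], a_slow, a_fast]), [lam_slow, lam_fast], rss)
    residuals = y - (
        coef[0] + a_slow * np.exp(-lam_slow * x) + a_fast * np.exp(-lam_fast * x)
    )
    return DecayFit(
        model="dual",
        alpha0=float(coef[0]),
        alpha1=float(a_slow),
        beta1=-lam_slow,
        alpha2=float(a_fast),
        beta2=-lam_fast,
        residuals=residuals,
        n_obs=x.size,
        k_params=5,
        rss=rss,
        cov=cov,
        converged=bool(sol.success and np.isfinite(rss)),
    )


def bic(fit: DecayFit) -> float:
    """``N ln(RSS/N) + k ln N`` with a documented floor at RSS -> 0."""
    if not fit.converged:
        raise ValueError("BIC of a non-converged fit is undefined")
    n = fit.n_obs
    rss = max(fit.rss, _RSS_FLOOR)
    return n * np.log(rss / n) + fit.k_params * np.log(n)


def select_model(single: DecayFit | None, dual: DecayFit | None):
    """Smaller-BIC model; ties and a non-converged dual go to single.

    Returns ``(selected_fit, delta_bic)`` with
    ``delta_bic = BIC_dual - BIC_single`` (positive favours single);
    ``delta_bic`` is NaN when one fit is unusable.
    """
    single_ok = single is not None and single.converged
    dual_ok = dual is not None and dual.converged
    if not single_ok and not dual_ok:
        raise FitError("neither model converged")
    if not dual_ok:
        return single, np.nan
    if not single_ok:
        return dual, np.nan
    delta = bic(dual) - bic(single)
    return (single if delta >= 0 else dual), float(delta)


def parameter_ci(fit: DecayFit, level: float = 0.95) -> dict:
    """Wald intervals from the Gaussian approximation of the posterior.

    Returns ``{name: (lo, hi)}``; a singular information matrix yields
    infinite intervals (flagged by width).
    """
    if not fit.converged:
        raise ValueError("no confidence intervals for a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = {}
    p = fit.params
    for i, name in enumerate(fit.param_names):
        if fit.cov is None:
            out[name] = (-np.inf, np.inf)
        else:
            se = np.sqrt(max(fit.cov[i, i], 0.0))
            out[name] = (p[i] - z * se, p[i] + z * se)
    return out


def bootstrap_decay(
    series: DecaySeries,
    n_iter: int = 10_000,
    seed: int | None = None,
    model: str = "single",
    level: float = 0.95,
) -> BootstrapResult:
    """Participant-resampling bootstrap of the decay parameters.

    Each iteration draws participants with replacement, averages the
    resampled cohort, and refits (warm-started at the point fit).
    Non-converged iterations are discarded and counted.
    """
    if series.per_participant is None or series.per_participant.shape[0] < 2:
        raise ValueError("bootstrap needs a per-participant matrix with >= 2 rows")
    fitter = fit_single_rate if model == "single" else fit_dual_rate
    point = fitter(series)
    init = point.params if point.converged else None
    rng = np.random.default_rng(seed)
    P = series.per_participant.shape[0]
    draws = []
    for _ in range(n_iter):
        idx = rng.integers(0, P, size=P)
        y_bar = series.per_participant[idx].mean(axis=0)
        try:
            f = fitter(DecaySeries(series.x, y_bar), init=init)
        except Exception:
            continue
        if f.converged:
            draws.append(f.params)
    if not draws:
        raise FitError("all bootstrap iterations failed")
    draws = np.asarray(draws)
    qs = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    ci = {
        name: tuple(np.percentile(draws[:, i], qs))
        for i, name in enumerate(point.param_names)
    }
    return BootstrapResult(
        draws=draws,
        param_names=point.param_names,
        n_requested=n_iter,
        n_retained=draws.shape[0],
        ci=ci,
        level=level,
        seed=seed,
    )
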