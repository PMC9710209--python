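"""Kinetic analysis of thioflavin-T (ThT) aggregation traces.

Two regimes are analysed, mirroring seeded alpha-synuclein aggregation assays:

* **High seed** (~15% preformed fibrils): nucleation is negligible and the
  early reaction is pure elongation, ``dM/dt = 2 k+ P(0) m(0)``, so the first
  few points of the normalized trace are fitted with a straight line whose
  slope is the effective elongation rate.

* **Low seed** (~0.06% seeds) under mildly acidic conditions: secondary
  nucleation dominates and the normalized fibril mass follows a generalized
  logistic (Richards) curve

  .. math:: M(t) = 1 - \\left[1 + \\frac{c}{a} e^{\\kappa t}\\right]^{-1/c}

  with amplitude parameter ``a`` (``M(0) ~ 1/a``), effective growth rate
  ``kappa`` (a combination of elongation and secondary-nucleation rate
  constants) and fixed shape parameter ``c`` (default 0.3, corresponding to a
  secondary-nucleation reaction order of n2 = 4). The primary-nucleation
  combination is ``lambda = kappa * sqrt(2/a)``, obtained by matching the
  early-time limit ``M(t) ~ (lambda^2 / 2 kappa^2) e^{kappa t}``.

From the fitted curve the monomer fraction is ``m(t) = 1 - M(t)`` and the
fibril number concentration (normalized units) is ``P(t) = M'(t) / (r+ m(t))``
with ``r+ = 2 k+ m_tot``; its derivative dP/dt evaluated at the half-time is
used as an effective fibril amplification rate, reported relative to the
antibody-free control.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateControlError,
    DegenerateTraceError,
    InvalidInputError,
)

__all__ = [
    "ThTTrace",
    "ElongationFit",
    "LogisticFit",
    "AmplificationRate",
    "fibril_mass",
    "fibril_mass_rate",
    "monomer_fraction",
    "fibril_number",
    "primary_nucleation_combination",
    "amplification_at_half_time",
    "GeneralizedLogisticModel",
    "ElongationRateModel",
    "normalize_trace",
    "fit_elongation",
    "relative_elongation",
    "fit_logistic",
    "half_time",
    "amplification_rate",
    "relative_amplification",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class ThTTrace:
    """One well's ThT fluorescence time course plus condition metadata.

    ``time`` is in minutes and must be strictly increasing. ``signal`` is raw
    fluorescence (arbitrary units) or, if ``normalized``, fibril mass fraction
    expected to lie in [-0.1, 1.1] (noise tolerance).
    """

    time: np.ndarray
    signal: np.ndarray
    condition: str = "control"
    seed_fraction: float | None = None
    m_tot: float | None = None
    replicate: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise InvalidInputError("time and signal must be matching 1-D arrays")
        if self.time.size < 2 or not np.all(np.diff(self.time) > 0):
            raise InvalidInputError("time must be strictly increasing")
        if self.normalized and (
            self.signal.min() < -0.1 or self.signal.max() > 1.1
        ):
            raise InvalidInputError(
                "normalized signal outside [-0.1, 1.1]; trace looks raw"
            )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class ElongationFit:
    """Linear fit of the initial elongation phase of a high-seed trace.

    ``slope`` equals the unresolved product 2*k+*P(0)*m(0) on normalized data
    and is only meaningful relative to the control condition.
    """

    slope: float
    intercept: float
    n_points_used: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points_used < 2:
            raise InvalidInputError("elongation fit needs at least 2 points")


@dataclass
class LogisticFit:
    """Fitted generalized-logistic parameters for one normalized trace set."""

    a: float
    kappa: float
    c: float
    lambda_: float
    rss: float
    r_squared: float
    t_half: float
    converged: bool
    message: str = ""

    def mass(self, t) -> np.ndarray:
        """Fitted fibril mass fraction M(t)."""
        return fibril_mass(t, self.a, self.kappa, self.c)


@dataclass
class AmplificationRate:
    """Effective fibril amplification rate dP/dt at the reaction half-time."""

    dP_dt_half: float
    relative: float | None = None

    def __post_init__(self) -> None:
        if self.dP_dt_half < 0:
            raise InvalidInputError("amplification rate must be non-negative")


# ---------------------------------------------------------------------------
# closed-form model functions (one per model quantity)
# ---------------------------------------------------------------------------


def _log_u(t, a, kappa, c):
    # u = (c/a) e^{kappa t}; work in logs for overflow safety
    return np.log(c / a) + kappa * np.asarray(t, dtype=float)


def fibril_mass(t, a: float, kappa: float, c: float = 0.3) -> np.ndarray:
    """Normalized fibril mass M(t) of the generalized logistic model."""
    _check_params(a, kappa, c)
    log1pu = np.logaddexp(0.0, _log_u(t, a, kappa, c))
    return 1.0 - np.exp(-log1pu / c)


def fibril_mass_rate(t, a: float, kappa: float, c: float = 0.3) -> np.ndarray:
    """dM/dt = (kappa/c) * u * (1+u)^(-(1+1/c))."""
    _check_params(a, kappa, c)
    log_u = _log_u(t, a, kappa, c)
    log1pu = np.logaddexp(0.0, log_u)
    return (kappa / c) * np.exp(log_u - (1.0 + 1.0 / c) * log1pu)


def monomer_fraction(t, a: float, kappa: float, c: float = 0.3) -> np.ndarray:
    """Monomer fraction m(t) = 1 - M(t) = (1+u)^(-1/c), cancellation-free."""
    _check_params(a, kappa, c)
    log1pu = np.logaddexp(0.0, _log_u(t, a, kappa, c))
    return np.exp(-log1pu / c)


def fibril_number(
    t, a: float, kappa: float, c: float = 0.3, r_plus: float = 1.0
) -> np.ndarray:
    """Fibril number concentration P(t) = M'(t) / (r+ * m(t)), normalized units.

    Closed form: P = kappa * u / (r+ * c * (1 + u)) with u = (c/a) e^{kappa t}.
    """
    if r_plus <= 0:
        raise InvalidInputError("r_plus must be positive")
    log_u = _log_u(t, a, kappa, c)
    log1pu = np.logaddexp(0.0, log_u)
    return (kappa / (r_plus * c)) * np.exp(log_u - log1pu)


def primary_nucleation_combination(a: float, kappa: float) -> float:
    """lambda = kappa * sqrt(2/a), from the early-time limit M ~ (lambda^2/2 kappa^2) e^{kappa t}."""
    if a <= 0 or kappa <= 0:
        raise InvalidInputError("a and kappa must be positive")
    return kappa * float(np.sqrt(2.0 / a))


def amplification_at_half_time(
    a: float, kappa: float, c: float = 0.3, r_plus: float = 1.0
) -> float:
    """dP/dt evaluated at t_half, where u = 2^c - 1.

    dP/dt = kappa^2 * u / (r+ * c * (1+u)^2).
    """
    _check_params(a, kappa, c)
    if r_plus <= 0:
        raise InvalidInputError("r_plus must be positive")
    u = 2.0**c - 1.0
    return kappa**2 * u / (r_plus * c * (1.0 + u) ** 2)


def _check_params(a, kappa, c):
    if a <= 0 or kappa <= 0 or not (0 < c <= 1):
        raise InvalidInputError(
            f"invalid logistic parameters a={a}, kappa={kappa}, c={c}"
        )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


class ElongationRateModel(BaseEstimator):
    """Ordinary least-squares line through the first ``n_points`` samples.

    Parameters
    ----------
    n_points : int, default 6
        Number of initial samples to fit (the assay samples once per minute,
        so the default covers the first six minutes of the seeded reaction).

    Attributes
    ----------
    slope_ : float
        Initial elongation rate d(signal)/dt (per minute).
    intercept_ : float
    r_squared_ : float
    n_points_used_ : int
    """

    def __init__(self, n_points: int = 6):
        self.n_points = n_points

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if self.n_points < 2:
            raise InvalidInputError("n_points must be >= 2")
        if t.size < self.n_points or t.size != y.size:
            raise InvalidInputError("not enough samples for the fit window")
        ts, ys = t[: self.n_points], y[: self.n_points]
        res = stats.linregress(ts, ys)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        pred = self.slope_ * ts + self.intercept_
        rss = float(np.sum((ys - pred) ** 2))
        tss = float(np.sum((ys - ys.mean()) ** 2))
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else float("nan")
        self.n_points_used_ = int(self.n_points)
        return self

    def predict(self, t):
        return self.slope_ * np.asarray(t, dtype=float) + self.intercept_


class GeneralizedLogisticModel(BaseEstimator):
    """Bounded nonlinear least-squares fit of the generalized logistic curve.

    ``c`` is held fixed (default 0.3); only ``(a, kappa)`` are free. Replicate
    traces may be passed as lists of arrays and are fitted jointly by pooling
    residuals. A fit whose half-time falls outside the observed time window is
    flagged ``converged_ = False`` (the half-time is then not identifiable
    from the data); optimizer failures are likewise reported as a
    non-converged result rather than an exception.

    Attributes (after ``fit``): ``a_``, ``kappa_``, ``c_``, ``lambda_``,
    ``rss_``, ``r_squared_``, ``t_half_``, ``converged_``, ``message_``.
    """

    A_BOUNDS = (1e-6, 1e6)
    KAPPA_BOUNDS = (1e-9, 10.0)

    def __init__(self, c: float = 0.3):
        self.c = c

    # -- helpers ------------------------------------------------------------
    @staticmethod
    def _pool(t, y):
        if isinstance(t, np.ndarray) and t.ndim == 1 and np.isscalar(t[0]):
            pass
        if np.ndim(t[0]) > 0:  # sequence of replicate arrays
            t_all = np.concatenate([np.asarray(ti, dtype=float) for ti in t])
            y_all = np.concatenate([np.asarray(yi, dtype=float) for yi in y])
        else:
            t_all = np.asarray(t, dtype=float)
            y_all = np.asarray(y, dtype=float)
        return t_all, y_all

    def _initial_guess(self, t, y):
        y0 = float(np.clip(y[: max(3, y.size // 100)].mean(), 1e-4, 0.5))
        a0 = 1.0 / y0
        # slope over a coarse stride to suppress noise amplification
        stride = max(1, y.size // 50)
        dy = (y[stride:] - y[:-stride]) / (t[stride:] - t[:-stride])
        slope_max = float(np.max(dy)) if dy.size else 0.0
        kappa0 = slope_max / 0.25 if slope_max > 0 else 1.0 / (t[-1] - t[0])
        return (
            float(np.clip(a0, *self.A_BOUNDS)),
            float(np.clip(kappa0, *self.KAPPA_BOUNDS)),
        )

    # -- API ----------------------------------------------------------------
    def fit(self, t, y):
        t_all, y_all = self._pool(t, y)
        if t_all.size < 10:
            raise InvalidInputError("need at least 10 samples to fit the sigmoid")
        order = np.argsort(t_all, kind="stable")
        t_all, y_all = t_all[order], y_all[order]
        self.c_ = float(self.c)
        if not (0 < self.c_ <= 1):
            raise InvalidInputError("c must lie in (0, 1]")

        p0 = self._initial_guess(t_all, y_all)
        lo = (self.A_BOUNDS[0], self.KAPPA_BOUNDS[0])
        hi = (self.A_BOUNDS[1], self.KAPPA_BOUNDS[1])
        converged, message = True, "converged"
        try:
            popt, _ = optimize.curve_fit(
                lambda tt, a, k: fibril_mass(tt, a, k, self.c_),
                t_all,
                y_all,
                p0=p0,
                bounds=(lo, hi),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
            a_hat, kappa_hat = float(popt[0]), float(popt[1])
        except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
            a_hat, kappa_hat = p0
            converged, message = False, f"optimizer failure: {exc}"

        self.a_, self.kappa_ = a_hat, kappa_hat
        pred = fibril_mass(t_all, a_hat, kappa_hat, self.c_)
        self.rss_ = float(np.sum((y_all - pred) ** 2))
        tss = float(np.sum((y_all - y_all.mean()) ** 2))
        self.r_squared_ = 1.0 - self.rss_ / tss if tss > 0 else float("nan")
        self.lambda_ = primary_nucleation_combination(a_hat, kappa_hat)
        self.t_half_ = _half_time_root(a_hat, kappa_hat, self.c_)
        if converged and not (0 < self.t_half_ <= t_all[-1]):
            converged = False
            message = (
                "half-time outside the observed window; sigmoid not "
                "identifiable from these data"
            )
        self.converged_ = converged
        self.message_ = message
        self.n_samples_ = int(t_all.size)
        return self

    def predict(self, t):
        return fibril_mass(t, self.a_, self.kappa_, self.c_)

    def to_fit(self) -> LogisticFit:
        return LogisticFit(
            a=self.a_,
            kappa=self.kappa_,
            c=self.c_,
            lambda_=self.lambda_,
            rss=self.rss_,
            r_squared=self.r_squared_,
            t_half=self.t_half_,
            converged=self.converged_,
            message=self.message_,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def normalize_trace(
    raw: ThTTrace, baseline_n: int = 3, plateau_n: int = 5
) -> ThTTrace:
    """Normalize a raw trace to [0, 1] using baseline and plateau windows.

    baseline = mean of the first ``baseline_n`` samples, plateau = mean of the
    last ``plateau_n``; output = (signal - baseline) / (plateau - baseline).
    """
    if raw.normalized:
        raise InvalidInputError("trace is already normalized")
    if len(raw) < baseline_n + plateau_n:
        raise InvalidInputError("trace too short for the requested windows")
    baseline = float(raw.signal[:baseline_n].mean())
    plateau = float(raw.signal[-plateau_n:].mean())
    if plateau <= baseline:
        raise DegenerateTraceError(
            f"plateau ({plateau:g}) <= baseline ({baseline:g}): no growth"
        )
    sig = (raw.signal - baseline) / (plateau - baseline)
    return replace(raw, signal=sig, normalized=True)


def fit_elongation(trace: ThTTrace, n_points: int = 6) -> ElongationFit:
    """Fit the initial linear elongation phase of a normalized high-seed trace."""
    if not trace.normalized:
        raise InvalidInputError("normalize the trace before fitting")
    model = ElongationRateModel(n_points=n_points).fit(trace.time, trace.signal)
    return ElongationFit(
        slope=model.slope_,
        intercept=model.intercept_,
        n_points_used=model.n_points_used_,
        r_squared=model.r_squared_,
    )


def _as_list(v):
    return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v]


def relative_elongation(
    fits: Mapping[str, ElongationFit | Sequence[ElongationFit]],
    control: str = "control",
) -> dict[str, np.ndarray]:
    """Divide each condition's slopes by the control mean slope.

    Returns per-condition arrays of ratios (one per replicate fit); the mean
    ratio of the control condition is exactly 1.
    """
    if control not in fits:
        raise InvalidInputError(f"control condition {control!r} missing")
    slopes = {k: np.array([f.slope for f in _as_list(v)]) for k, v in fits.items()}
    ctrl_mean = float(slopes[control].mean())
    if ctrl_mean <= 0:
        raise DegenerateControlError("control slope mean is not positive")
    return {k: s / ctrl_mean for k, s in slopes.items()}


def fit_logistic(
    traces: ThTTrace | Sequence[ThTTrace], c_fixed: float = 0.3
) -> LogisticFit:
    """Fit the generalized logistic to one trace or a pooled replicate set."""
    tr = _as_list(traces)
    for t in tr:
        if not t.normalized:
            raise InvalidInputError("all traces must be normalized first")
    model = GeneralizedLogisticModel(c=c_fixed).fit(
        [t.time for t in tr], [t.signal for t in tr]
    )
    return model.to_fit()


def _half_time_root(a: float, kappa: float, c: float) -> float:
    """Root-solve M(t) = 0.5 by bracketed bisection (unique by monotonicity)."""
    f = lambda t: fibril_mass(t, a, kappa, c) - 0.5
    if f(0.0) >= 0:  # trace starts at or above half of the plateau
        return 0.0
    hi = 1.0 / kappa
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12 / kappa:  # pragma: no cover - defensive
            return float("inf")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def half_time(fit: LogisticFit) -> float:
    """Time at which the fitted fibril mass reaches half of the plateau."""
    return _half_time_root(fit.a, fit.kappa, fit.c)


def amplification_rate(
    fit: LogisticFit, r_plus: float = 1.0, control_mean: float | None = None
) -> AmplificationRate:
    """Effective fibril amplification rate dP/dt at t_half (normalized units).

    When ``control_mean`` is supplied the relative value is filled in; use
    :func:`relative_amplification` to normalize a whole condition map.
    """
    value = amplification_at_half_time(fit.a, fit.kappa, fit.c, r_plus)
    rel = value / control_mean if control_mean else None
    return AmplificationRate(dP_dt_half=value, relative=rel)


def relative_amplification(
    rates: Mapping[str, AmplificationRate | Sequence[AmplificationRate]],
    control: str = "control",
) -> dict[str, np.ndarray]:
    """Normalize per-condition amplification rates to the control mean."""
    if control not in rates:
        raise InvalidInputError(f"control condition {control!r} missing")
    vals = {
        k: np.array([r.dP_dt_half for r in _as_list(v)]) for k, v in rates.items()
    }
    ctrl_mean = float(vals[control].mean())
    if ctrl_mean <= 0:
        raise DegenerateControlError("control amplification mean is not positive")
    return {k: v / ctrl_mean for k, v in vals.items()}
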