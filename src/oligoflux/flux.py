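"""Analytical flux toward oligomeric species, phi(t).

In the linear polymerisation picture every new fibril arises from an oligomer
generated on fibril surfaces (secondary nucleation, the *source*) and consumed
by elongation into mature fibrils (the *sink*). The net flux toward oligomers
is therefore the rate of change of the fibril number concentration,

.. math:: \\phi(t) = \\frac{d}{dt}\\,\\frac{M'(t)}{r_+\\,m(t)},

with ``m = 1 - M`` and ``r_+ = 2 k_+ m_tot`` the effective elongation rate.
Substituting the fitted generalized logistic for ``M(t)`` gives the closed
forms (``u = (c/a) e^{kappa t}``):

* profile:    ``phi(t)   = kappa^2 u / (r_+ c (1+u)^2)`` — a bell-shaped curve
* area:       ``phi_Area = kappa a / (r_+ c (a + c))``   (= P(inf) - P(0))
* peak time:  ``phi_Time = ln(a/c) / kappa``             (where u = 1)
* peak height:``phi_Peak = kappa^2 / (4 r_+ c)``

phi_Peak, phi_Area and phi_Time summarize, respectively, the maximal rate of
oligomer generation, the total number of oligomers formed over the reaction,
and when generation is fastest; each is reported relative to the mean of the
antibody-free control replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DegenerateControlError, InvalidInputError, NoPeakError
from .kinetics import ElongationFit, LogisticFit, _half_time_root

__all__ = [
    "FluxProfile",
    "NormalizedFluxMetrics",
    "oligomer_flux",
    "oligomer_flux_rate",
    "compute_flux",
    "flux_area",
    "flux_peak_time",
    "flux_peak_height",
    "normalize_metrics",
]


@dataclass
class FluxProfile:
    """phi(t) samples plus the three summary scalars."""

    t: np.ndarray
    phi: np.ndarray
    phi_peak: float
    phi_area: float
    phi_time: float
    r_plus_used: float
    condition: str = "control"
    replicate: int = 0


@dataclass
class NormalizedFluxMetrics:
    """Per-replicate flux summaries divided by the control means."""

    phi_peak_rel: np.ndarray
    phi_area_rel: np.ndarray
    phi_time_rel: np.ndarray


def _r_plus_value(r_plus) -> float:
    r = r_plus.slope if isinstance(r_plus, ElongationFit) else float(r_plus)
    if r <= 0:
        raise InvalidInputError("r_plus must be positive")
    return r


def _log_u(t, a, kappa, c):
    return np.log(c / a) + kappa * np.asarray(t, dtype=float)


def oligomer_flux(t, a, kappa, c=0.3, r_plus=1.0) -> np.ndarray:
    """phi(t) = kappa^2 u / (r+ c (1+u)^2), evaluated overflow-safely."""
    r = _r_plus_value(r_plus)
    log_u = _log_u(t, a, kappa, c)
    log1pu = np.logaddexp(0.0, log_u)
    return kappa**2 / (r * c) * np.exp(log_u - 2.0 * log1pu)


def oligomer_flux_rate(t, a, kappa, c=0.3, r_plus=1.0) -> np.ndarray:
    """dphi/dt = kappa^3 u (1-u) / (r+ c (1+u)^3); vanishes at u = 1."""
    r = _r_plus_value(r_plus)
    log_u = _log_u(t, a, kappa, c)
    log1pu = np.logaddexp(0.0, log_u)
    u_frac = np.exp(log_u - log1pu)  # u/(1+u), bounded
    one_minus = 1.0 - 2.0 * u_frac  # (1-u)/(1+u)
    return kappa**3 / (r * c) * np.exp(log_u - 2.0 * log1pu) * one_minus


def default_grid(fit: LogisticFit) -> np.ndarray:
    """t in [0, 5*t_half] at a pitch of t_half/1000 — captures the bell."""
    t_half = _half_time_root(fit.a, fit.kappa, fit.c)
    if not np.isfinite(t_half) or t_half <= 0:
        raise InvalidInputError("fit has no positive finite half-time")
    return np.arange(0.0, 5.0 * t_half + 1e-12, t_half / 1000.0)


def compute_flux(
    fit: LogisticFit,
    r_plus,
    t_grid: np.ndarray | None = None,
    condition: str | None = None,
    replicate: int = 0,
) -> FluxProfile:
    """Evaluate the flux profile and its summary scalars for one fit."""
    r = _r_plus_value(r_plus)
    t = default_grid(fit) if t_grid is None else np.asarray(t_grid, dtype=float)
    phi = oligomer_flux(t, fit.a, fit.kappa, fit.c, r)
    try:
        t_peak = flux_peak_time(fit, r)
        peak = float(oligomer_flux(t_peak, fit.a, fit.kappa, fit.c, r))
    except NoPeakError:
        t_peak = float(t[np.argmax(phi)])
        peak = float(phi.max())
    return FluxProfile(
        t=t,
        phi=phi,
        phi_peak=peak,
        phi_area=flux_area(fit, r),
        phi_time=t_peak,
        r_plus_used=r,
        condition=condition or "control",
        replicate=replicate,
    )


def flux_area(fit: LogisticFit, r_plus) -> float:
    """Closed-form integral of phi over [0, inf): kappa a / (r+ c (a + c))."""
    r = _r_plus_value(r_plus)
    return fit.kappa * fit.a / (r * fit.c * (fit.a + fit.c))


def flux_peak_time(fit: LogisticFit, r_plus) -> float:
    """Peak time of phi, found by bracketed root-finding of dphi/dt = 0.

    Bracket: [t_half/100, 5*t_half]. Raises :class:`NoPeakError` when dphi/dt
    does not change sign there (e.g. a <= c, peak before t = 0).
    """
    r = _r_plus_value(r_plus)
    t_half = _half_time_root(fit.a, fit.kappa, fit.c)
    if not np.isfinite(t_half) or t_half <= 0:
        raise NoPeakError("no positive half-time; flux peak undefined")
    lo, hi = t_half / 100.0, 5.0 * t_half
    f = lambda t: oligomer_flux_rate(t, fit.a, fit.kappa, fit.c, r)
    if f(lo) * f(hi) > 0:
        raise NoPeakError("dphi/dt does not change sign in the bracket")
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def flux_peak_height(fit: LogisticFit, r_plus) -> float:
    """phi evaluated at the peak time via the closed form (= kappa^2/(4 r+ c))."""
    r = _r_plus_value(r_plus)
    t_peak = flux_peak_time(fit, r)
    return float(oligomer_flux(t_peak, fit.a, fit.kappa, fit.c, r))


def normalize_metrics(
    profiles: Mapping[str, Sequence[FluxProfile] | FluxProfile],
    control: str = "control",
) -> dict[str, NormalizedFluxMetrics]:
    """Divide each condition's phi_Peak/phi_Area/phi_Time by the control means."""
    if control not in profiles:
        raise InvalidInputError(f"control condition {control!r} missing")

    def as_list(v):
        return list(v) if isinstance(v, (list, tuple)) else [v]

    if len(as_list(profiles[control])) < 1:
        raise InvalidInputError("control must have at least one replicate")
    stacks = {
        k: {
            "peak": np.array([p.phi_peak for p in as_list(v)]),
            "area": np.array([p.phi_area for p in as_list(v)]),
            "time": np.array([p.phi_time for p in as_list(v)]),
        }
        for k, v in profiles.items()
    }
    ctrl = stacks[control]
    means = {m: float(ctrl[m].mean()) for m in ("peak", "area", "time")}
    if any(v == 0 for v in means.values()):
        raise DegenerateControlError("control mean flux metric is zero")
    return {
        k: NormalizedFluxMetrics(
            phi_peak_rel=s["peak"] / means["peak"],
            phi_area_rel=s["area"] / means["area"],
            phi_time_rel=s["time"] / means["time"],
        )
        for k, s in stacks.items()
    }
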