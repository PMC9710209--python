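"""Saturation-binding (MST) fits and biolayer-interferometry (BLI) correction.

Microscale-thermophoresis titrations are fitted with the one-site saturation
binding equation ``Y = B_Max * x / (K_D + x)``; before fitting, the lowest
signal of a titration is conventionally shifted to zero (:func:`zero_floor`),
matching how such dose-response curves are usually preprocessed. A
three-parameter variant with a free offset is available for robustness
checks. BLI sensor traces are corrected by subtracting a reference sensor
and then the mean of the trace's own baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .exceptions import AlignmentError, InvalidInputError

__all__ = [
    "BindingCurve",
    "BindingFit",
    "BliTrace",
    "SaturationBindingModel",
    "fit_saturation",
    "zero_floor",
    "bli_reference_subtract",
]


@dataclass
class BindingCurve:
    """A ligand titration: concentrations ``x`` (uM) and responses ``y``."""

    x: np.ndarray
    y: np.ndarray
    zeroed: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InvalidInputError("x and y must be matching 1-D arrays")
        if self.x.size < 4:
            raise InvalidInputError("need at least 4 titration points")
        if np.any(self.x <= 0):
            raise InvalidInputError("concentrations must be positive")
        d = np.diff(self.x)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("concentrations must be strictly monotone")


@dataclass
class BindingFit:
    """Result of a saturation-binding fit."""

    kd: float
    bmax: float
    r_squared: float
    converged: bool
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.converged and self.kd <= 0:
            raise InvalidInputError("converged fit must have kd > 0")


@dataclass
class BliTrace:
    """A BLI sensorgram with per-sample phase labels.

    ``phase`` entries are 'baseline', 'association' or 'dissociation' and each
    label must occupy one contiguous block.
    """

    t: np.ndarray
    signal: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.t.shape == self.signal.shape == self.phase.shape):
            raise InvalidInputError("t, signal and phase must match in shape")
        if not np.all(np.diff(self.t) > 0):
            raise InvalidInputError("time must be strictly increasing")
        # each phase label must be contiguous
        labels = [self.phase[0]]
        for p in self.phase[1:]:
            if p != labels[-1]:
                labels.append(p)
        if len(labels) != len(set(labels)):
            raise InvalidInputError("phase labels must be contiguous blocks")


def saturation_response(x, kd: float, bmax: float, offset: float = 0.0):
    """One-site specific binding: Y = B_Max * x / (K_D + x) + offset."""
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x) + offset


class SaturationBindingModel(BaseEstimator):
    """Least-squares estimator for the one-site saturation binding equation.

    Parameters
    ----------
    with_offset : bool, default False
        Fit a third, additive-offset parameter. The default two-parameter
        form matches the equation used for pre-floored titrations.

    Attributes: ``kd_``, ``bmax_``, ``offset_``, ``r_squared_``, ``converged_``.
    """

    def __init__(self, with_offset: bool = False):
        self.with_offset = with_offset

    def fit(self, x, y):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size < 4 or x.size != y.size:
            raise InvalidInputError("need at least 4 (x, y) points")
        if np.any(x <= 0):
            raise InvalidInputError("concentrations must be positive")

        kd0 = float(np.exp(np.mean(np.log(x))))  # geometric mean, scale-free
        span = float(y.max() - y.min())
        bmax0 = span if span > 0 else max(abs(y.max()), 1.0)
        self.converged_ = True
        try:
            if self.with_offset:
                popt, _ = optimize.curve_fit(
                    saturation_response,
                    x,
                    y,
                    p0=(kd0, bmax0, float(y.min())),
                    bounds=((1e-12, 1e-12, -np.inf), (np.inf, np.inf, np.inf)),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    max_nfev=20000,
                )
                self.kd_, self.bmax_, self.offset_ = map(float, popt)
            else:
                popt, _ = optimize.curve_fit(
                    lambda xx, kd, bmax: saturation_response(xx, kd, bmax),
                    x,
                    y,
                    p0=(kd0, bmax0),
                    bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    max_nfev=20000,
                )
                self.kd_, self.bmax_ = map(float, popt)
                self.offset_ = 0.0
        except (RuntimeError, ValueError):
            self.kd_, self.bmax_, self.offset_ = kd0, bmax0, 0.0
            self.converged_ = False

        pred = saturation_response(x, self.kd_, self.bmax_, self.offset_)
        rss = float(np.sum((y - pred) ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else float("nan")
        return self

    def predict(self, x):
        return saturation_response(x, self.kd_, self.bmax_, self.offset_)


def fit_saturation(curve: BindingCurve, with_offset: bool = False) -> BindingFit:
    """Fit K_D and B_Max to a titration; non-convergence is a value, not an error."""
    model = SaturationBindingModel(with_offset=with_offset).fit(curve.x, curve.y)
    return BindingFit(
        kd=model.kd_,
        bmax=model.bmax_,
        r_squared=model.r_squared_,
        converged=model.converged_,
        offset=model.offset_,
    )


def zero_floor(curve: BindingCurve) -> BindingCurve:
    """Shift responses so the lowest signal sits at zero (idempotent)."""
    return replace(curve, y=curve.y - float(curve.y.min()), zeroed=True)


def bli_reference_subtract(
    sample: BliTrace,
    reference: BliTrace,
    baseline_window: tuple[float, float] | None = None,
) -> BliTrace:
    """Reference-subtract and baseline-correct a BLI sensorgram.

    The reference trace is linearly interpolated onto the sample's time grid
    (their time ranges must overlap the sample's fully), subtracted, and the
    mean of the corrected trace over its own baseline window is removed so
    the association phase starts near zero. ``baseline_window`` is a
    ``(t0, t1)`` interval in seconds; by default the samples labelled
    'baseline' are used.
    """
    if sample.t[0] < reference.t[0] - 1e-9 or sample.t[-1] > reference.t[-1] + 1e-9:
        raise AlignmentError("reference does not cover the sample's time range")
    ref = np.interp(sample.t, reference.t, reference.signal)
    corrected = sample.signal - ref
    if baseline_window is not None:
        mask = (sample.t >= baseline_window[0]) & (sample.t <= baseline_window[1])
    else:
        mask = sample.phase == "baseline"
    if not np.any(mask):
        raise InvalidInputError("empty baseline window")
    corrected = corrected - float(corrected[mask].mean())
    return BliTrace(t=sample.t.copy(), signal=corrected, phase=sample.phase.copy())
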