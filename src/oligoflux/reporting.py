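"""Group comparisons against the antibody-free control and star labelling.

The study's figures report a one-way ANOVA with p-values quoted per condition
against the control mean. The omnibus F-test is computed first; per-condition
p-values then come from two-sided Welch t-tests versus the control (no
multiplicity correction, flagged in the result metadata), with a
Dunnett-style many-to-one option available.

Two star conventions appear in the source figures: a four-tier map
(* p<0.1, ** p<0.01, *** p<0.001, **** p<0.0001) and a three-tier map without
the p<0.1 level. The four-tier map is the default; boundary values fall to
the weaker category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateVarianceError, InvalidInputError

__all__ = [
    "GroupComparison",
    "AnovaResult",
    "anova_vs_control",
    "significance_stars",
    "STAR_SCHEMES",
]

# thresholds are strict upper bounds, checked from the most significant tier
STAR_SCHEMES: dict[str, list[tuple[float, str]]] = {
    "four_tier": [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.1, "*")],
    "three_tier": [(1e-4, "****"), (1e-3, "***"), (1e-2, "**")],
}


@dataclass
class GroupComparison:
    """One condition's summary and its comparison against the control."""

    condition: str
    n: int
    mean: float
    sd: float
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        if np.isfinite(self.p_value) and not 0 <= self.p_value <= 1:
            raise InvalidInputError("p-value must lie in [0, 1]")


@dataclass
class AnovaResult:
    """Omnibus one-way ANOVA plus per-condition control comparisons."""

    f_statistic: float
    p_omnibus: float
    comparisons: list[GroupComparison]
    control: str
    posthoc: str
    multiplicity_corrected: bool
    notes: str = ""


def significance_stars(p: float, scheme: str = "four_tier") -> str:
    """Map a p-value to its significance label ('ns' when not significant)."""
    if not np.isfinite(p) or not 0 <= p <= 1:
        raise InvalidInputError(f"p must lie in [0, 1], got {p!r}")
    if scheme not in STAR_SCHEMES:
        raise InvalidInputError(f"unknown star scheme {scheme!r}")
    label = "ns"
    for threshold, stars in reversed(STAR_SCHEMES[scheme]):
        if p < threshold:  # boundary values fall to the weaker category
            label = stars
    return label


def anova_vs_control(
    groups: Mapping[str, Sequence[float]],
    control: str = "control",
    scheme: str = "four_tier",
    posthoc: str = "welch",
) -> AnovaResult:
    """One-way ANOVA with per-condition comparisons against the control.

    ``posthoc='welch'`` (default): two-sided Welch t-tests versus the control,
    uncorrected for multiplicity (as quoted in the source figures; flagged in
    the result). ``posthoc='dunnett'``: Dunnett's many-to-one procedure.
    Deterministic given the inputs. Raises
    :class:`~oligoflux.exceptions.DegenerateVarianceError` when every group
    has zero within-group variance.
    """
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    if control not in groups:
        raise InvalidInputError(f"control condition {control!r} missing")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidInputError(f"group {k!r} needs n >= 2")
    if all(np.var(v) == 0 for v in arrays.values()):
        raise DegenerateVarianceError(
            "all groups have zero within-group variance; F is undefined"
        )
    f_stat, p_omni = stats.f_oneway(*arrays.values())

    others = [k for k in arrays if k != control]
    ctrl = arrays[control]
    if posthoc == "dunnett":
        res = stats.dunnett(*(arrays[k] for k in others), control=ctrl)
        pvals = dict(zip(others, np.asarray(res.pvalue, dtype=float)))
        corrected = True
    elif posthoc == "welch":
        pvals = {
            k: float(stats.ttest_ind(arrays[k], ctrl, equal_var=False).pvalue)
            for k in others
        }
        corrected = False
    else:
        raise InvalidInputError("posthoc must be 'welch' or 'dunnett'")

    comparisons = [
        GroupComparison(
            condition=control,
            n=int(ctrl.size),
            mean=float(ctrl.mean()),
            sd=float(ctrl.std(ddof=1)),
            p_value=float("nan"),
            stars="",
        )
    ]
    for k in others:
        v = arrays[k]
        p = pvals[k]
        p = float(min(max(p, 0.0), 1.0))
        comparisons.append(
            GroupComparison(
                condition=k,
                n=int(v.size),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)),
                p_value=p,
                stars=significance_stars(p, scheme=scheme),
            )
        )
    return AnovaResult(
        f_statistic=float(f_stat),
        p_omnibus=float(p_omni),
        comparisons=comparisons,
        control=control,
        posthoc=posthoc,
        multiplicity_corrected=corrected,
        notes="per-condition p-values are uncorrected" if not corrected else "",
    )
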