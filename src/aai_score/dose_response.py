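"""Per-group, per-analyte dose-response slope fits.

Each (group, analyte) cell is fit by ordinary least squares of the raw
fold-change response against the raw allergen dose (ug); although such data
are customarily plotted on log axes, the slope itself is estimated on the
untransformed values, every mouse contributing one point.  The two-sided
t-test of slope != 0 supplies the p-value consumed by the composite
susceptibility score.

Dose-0 (PBS) points are excluded by default: the PBS level is the
normalization anchor (fold change 1 by construction), not a response
measurement.  Set ``include_dose_zero=True`` to keep them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateDesignError,
    InputValidationError,
    InsufficientDataError,
    MissingDataError,
    UndefinedInverseError,
)

__all__ = ["ResponseRecord", "SlopeFit", "fit_slope", "fit_slope_xy", "inverse_slope", "fit_all"]


@dataclass(frozen=True)
class ResponseRecord:
    """One normalized response: fold change over PBS for one mouse x analyte."""

    mouse_id: str
    group: str
    dose: float
    analyte: str
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InputValidationError(
                f"mouse {self.mouse_id!r}: dose must be finite and non-negative, got {self.dose!r}"
            )
        if not math.isfinite(self.value) or self.value <= 0:
            raise InputValidationError(
                f"mouse {self.mouse_id!r} analyte {self.analyte!r}: fold change must be "
                f"finite and positive, got {self.value!r}"
            )


@dataclass(frozen=True)
class SlopeFit:
    """OLS dose-response fit for one group x analyte.

    ``slope`` has units of fold change per ug; ``p_value`` is the (default
    two-sided) test of slope != 0 on ``df = n − 2`` degrees of freedom.
    ``perfect_fit`` marks a zero-residual fit, whose p-value is reported as
    exactly 0 (nonzero slope) or 1 (constant response) rather than raising.
    """

    group: str
    analyte: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    df: int
    p_value: float
    perfect_fit: bool = False


# residual sums of squares below this fraction of the response scale count as exact fits
_PERFECT_FIT_RTOL = 1e-12


def fit_slope_xy(
    doses: Sequence[float],
    values: Sequence[float],
    group: str = "",
    analyte: str = "",
    one_sided: bool = False,
) -> SlopeFit:
    """Closed-form OLS of ``values`` on ``doses`` with the slope t-test.

    The array-level core of :func:`fit_slope`; no dose-0 filtering is applied.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputValidationError("doses and values must be 1-D and equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputValidationError("doses and values must be finite")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"{group}/{analyte}: need >= 3 points, got {n}")
    if np.unique(x).size < 2:
        raise DegenerateDesignError(f"{group}/{analyte}: all doses identical ({x[0]:g})")

    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float((resid**2).sum())
    df = n - 2

    scale = max(1.0, float((y**2).sum()))
    if sse <= _PERFECT_FIT_RTOL * scale:
        # exact fit: a nonzero slope is "infinitely" significant, a constant
        # response carries no evidence of any slope at all
        if abs(slope) * (x.max() - x.min()) <= math.sqrt(_PERFECT_FIT_RTOL * scale):
            return SlopeFit(group, analyte, n, 0.0, ybar, 0.0, 0.0, df, 1.0, True)
        return SlopeFit(group, analyte, n, slope, intercept, 0.0, math.inf, df, 0.0, True)

    sigma2 = sse / df
    slope_se = math.sqrt(sigma2 / sxx)
    t_stat = slope / slope_se
    if one_sided:
        p_value = float(stats.t.sf(t_stat, df))
    else:
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
    p_value = min(p_value, 1.0)
    return SlopeFit(group, analyte, n, slope, intercept, slope_se, t_stat, df, p_value, False)


def fit_slope(
    records: Iterable[ResponseRecord],
    include_dose_zero: bool = False,
    one_sided: bool = False,
    log_log: bool = False,
) -> SlopeFit:
    """Fit the dose-response slope for one group x analyte.

    Parameters
    ----------
    records
        Response records, all from a single (group, analyte) cell.
    include_dose_zero
        Keep the PBS (dose 0) anchor points in the regression.  Off by
        default; see the module docstring.
    one_sided
        Report the one-sided p-value for slope > 0 instead of the default
        two-sided test.
    log_log
        Fit log10(value) on log10(dose) instead of the raw scales.  Forces
        exclusion of dose-0 points (log of 0 is undefined).
    """
    recs = list(records)
    if not recs:
        raise InsufficientDataError("no response records supplied")
    groups = {r.group for r in recs}
    analytes = {r.analyte for r in recs}
    if len(groups) > 1 or len(analytes) > 1:
        raise InputValidationError(
            f"fit_slope expects a single group x analyte cell, got groups={sorted(groups)} "
            f"analytes={sorted(analytes)}"
        )
    if log_log:
        include_dose_zero = False
    if not include_dose_zero:
        recs = [r for r in recs if r.dose != 0]
    if len(recs) < 3:
        raise InsufficientDataError(
            f"{groups.pop()}/{analytes.pop()}: fewer than 3 usable points after dose-0 filtering"
        )
    x = [r.dose for r in recs]
    y = [r.value for r in recs]
    if log_log:
        x = [math.log10(v) for v in x]
        y = [math.log10(v) for v in y]
    return fit_slope_xy(x, y, group=groups.pop(), analyte=analytes.pop(), one_sided=one_sided)


def inverse_slope(fit: SlopeFit) -> float:
    """Reciprocal of the fitted slope (resistance-like transform: larger = flatter)."""
    if fit.slope == 0:
        raise UndefinedInverseError(f"{fit.group}/{fit.analyte}: slope is exactly 0")
    return 1.0 / fit.slope


def fit_all(
    records: Iterable[ResponseRecord],
    analytes: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
    **fit_kwargs,
) -> list[SlopeFit]:
    """One :func:`fit_slope` per requested group x analyte, ordered lexicographically.

    ``analytes``/``groups`` default to every value present in ``records``; a
    requested cell with no data raises :class:`MissingDataError` listing all
    missing cells.
    """
    recs = list(records)
    if groups is None:
        groups = sorted({r.group for r in recs})
    if analytes is None:
        analytes = sorted({r.analyte for r in recs})
    cells: dict[tuple[str, str], list[ResponseRecord]] = {}
    for r in recs:
        cells.setdefault((r.group, r.analyte), []).append(r)
    missing = [
        (g, a) for g in groups for a in analytes if not cells.get((g, a))
    ]
    if missing:
        raise MissingDataError(
            "missing group x analyte cells: " + ", ".join(f"{g}/{a}" for g, a in missing)
        )
    return [
        fit_slope(cells[(g, a)], **fit_kwargs)
        for g in sorted(groups)
        for a in sorted(analytes)
    ]
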