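"""Airway-hyperresponsiveness summaries: trapezoidal AUC of Rrs vs methacholine.

Respiratory-system resistance (Rrs, cm H2O/mL) is measured at increasing
aerosolized methacholine concentrations (typically 1-100 mg/mL, optionally a
PBS/0 point).  The per-mouse summary is the trapezoidal area under the
Rrs-vs-concentration curve on a linear concentration axis, in units of
(cm H2O/mL) x (mg/mL); group-level reporting is the mean and SD of the
per-mouse AUCs within each group x allergen-dose cell.

No extrapolation is performed below the lowest measured concentration, and
no parametric response shape (sigmoid/EC50) is fitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import InputValidationError, InsufficientDataError

__all__ = ["AhrCurve", "auc_trapezoid", "auc_table", "auc_by_group"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AhrCurve:
    """One mouse's Rrs responses over a strictly ascending methacholine series."""

    mouse_id: str
    group: str
    hdm_dose: float
    mch_concentrations: tuple[float, ...]
    rrs_values: tuple[float, ...]

    def __post_init__(self) -> None:
        c = tuple(float(v) for v in self.mch_concentrations)
        r = tuple(float(v) for v in self.rrs_values)
        object.__setattr__(self, "mch_concentrations", c)
        object.__setattr__(self, "rrs_values", r)
        if len(c) != len(r):
            raise InputValidationError(
                f"mouse {self.mouse_id!r}: {len(c)} concentrations but {len(r)} Rrs values"
            )
        if len(c) < 2:
            raise InsufficientDataError(f"mouse {self.mouse_id!r}: need >= 2 curve points")
        if any(not math.isfinite(v) for v in c) or any(not math.isfinite(v) for v in r):
            raise InputValidationError(f"mouse {self.mouse_id!r}: non-finite curve value")
        if any(b <= a for a, b in zip(c, c[1:])):
            raise InputValidationError(
                f"mouse {self.mouse_id!r}: methacholine concentrations must be strictly ascending"
            )
        if any(v < 0 for v in r):
            raise InputValidationError(f"mouse {self.mouse_id!r}: negative Rrs value")


def auc_trapezoid(curve: AhrCurve) -> float:
    """Trapezoidal integral of Rrs over the linear concentration axis."""
    return float(np.trapezoid(curve.rrs_values, curve.mch_concentrations))


def auc_table(curves: Iterable[AhrCurve]) -> pd.DataFrame:
    """Per-mouse AUC, one row per curve."""
    rows = [
        {
            "mouse_id": c.mouse_id,
            "group": c.group,
            "hdm_dose_ug": c.hdm_dose,
            "auc": auc_trapezoid(c),
        }
        for c in curves
    ]
    if not rows:
        raise InsufficientDataError("no AHR curves supplied")
    return pd.DataFrame(rows)


def auc_by_group(curves: Iterable[AhrCurve]) -> pd.DataFrame:
    """Mean and SD of per-mouse AUCs per group x allergen dose.

    SD uses the n−1 denominator; a single-mouse cell reports SD 0.  Rows are
    ordered by (group, hdm_dose_ug).
    """
    per_mouse = auc_table(curves)
    out = (
        per_mouse.groupby(["group", "hdm_dose_ug"], as_index=False)["auc"]
        .agg(n="count", auc_mean="mean", auc_sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
        .sort_values(["group", "hdm_dose_ug"], ignore_index=True)
    )
    return out
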