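"""Tidy-CSV readers/writers and Newick output.

All tables are long-format UTF-8 CSV with "." as the decimal separator, one
fact per row.  Readers validate the documented schema: missing required
columns raise, unknown extra columns are kept and logged as a warning, and
value-level violations name the offending row.

Schemas
-------
C_T table          sample_id, group, dose_ug, gene, ct          (replicates = repeated rows)
response table     mouse_id, group, dose_ug, analyte, fold_change
AHR table          mouse_id, group, hdm_dose_ug, mch_mg_per_ml, rrs
fold-change table  sample_id, group, dose_ug, analyte, delta_ct, delta_delta_ct, fold_change
slope-fit table    group, analyte, n, slope, intercept, slope_se, t_stat, df, p_value,
                   perfect_fit, inverse_slope
score table        group, analytes_used, p_values, score, alpha, cutoff, label
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .ahr import AhrCurve
from .dose_response import ResponseRecord, SlopeFit
from .exceptions import InputValidationError
from .qpcr import CtRecord, FoldChangeResult
from .score import ScoreResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_response_table",
    "write_response_table",
    "read_ahr_table",
    "write_ahr_table",
    "fold_changes_to_frame",
    "fits_to_frame",
    "frame_to_fits",
    "scores_to_frame",
    "write_newick",
    "load_config",
]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip: the default float parser can be off by 1 ulp, breaking
        # read(write(x)) = x
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise InputValidationError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra columns %s (preserved on passthrough)", path, extra)
    if df.empty:
        raise InputValidationError(f"{path}: no data rows")
    return df


def _row_err(path, idx, msg, exc) -> InputValidationError:
    return InputValidationError(f"{path}, row {idx + 2}: {msg}: {exc}")  # +2: header + 1-basing


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a long-format C_T table; repeated rows become replicate wells."""
    df = _read_csv(path, ["sample_id", "group", "dose_ug", "gene", "ct"])
    pooled: dict[tuple[str, str, float, str], list[float]] = defaultdict(list)
    order: list[tuple[str, str, float, str]] = []
    for idx, row in df.iterrows():
        try:
            key = (str(row["sample_id"]), str(row["group"]), float(row["dose_ug"]), str(row["gene"]))
            ct = float(row["ct"])
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"ct must be a positive finite cycle count, got {ct}")
        except (TypeError, ValueError) as exc:
            raise _row_err(path, idx, "invalid C_T row", exc) from None
        if key not in pooled:
            order.append(key)
        pooled[key].append(ct)
    records = []
    for key in order:
        sample, group, dose, gene = key
        try:
            records.append(CtRecord(sample, group, dose, gene, tuple(pooled[key])))
        except InputValidationError as exc:
            raise InputValidationError(f"{path}: {exc}") from None
    return records


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "group": r.group, "dose_ug": r.dose, "gene": r.gene, "ct": ct}
        for r in records
        for ct in r.ct_replicates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_response_table(path: str | Path) -> list[ResponseRecord]:
    df = _read_csv(path, ["mouse_id", "group", "dose_ug", "analyte", "fold_change"])
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                ResponseRecord(
                    mouse_id=str(row["mouse_id"]),
                    group=str(row["group"]),
                    dose=float(row["dose_ug"]),
                    analyte=str(row["analyte"]),
                    value=float(row["fold_change"]),
                )
            )
        except (TypeError, ValueError, InputValidationError) as exc:
            raise _row_err(path, idx, "invalid response row", exc) from None
    return records


def write_response_table(records: Iterable[ResponseRecord], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": r.mouse_id,
            "group": r.group,
            "dose_ug": r.dose,
            "analyte": r.analyte,
            "fold_change": r.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ahr_table(path: str | Path) -> list[AhrCurve]:
    """Read per-point AHR rows and assemble one curve per mouse x HDM dose."""
    df = _read_csv(path, ["mouse_id", "group", "hdm_dose_ug", "mch_mg_per_ml", "rrs"])
    curves = []
    for (mouse, group, hdm), sub in df.groupby(["mouse_id", "group", "hdm_dose_ug"], sort=True):
        sub = sub.sort_values("mch_mg_per_ml")
        try:
            curves.append(
                AhrCurve(
                    mouse_id=str(mouse),
                    group=str(group),
                    hdm_dose=float(hdm),
                    mch_concentrations=tuple(float(v) for v in sub["mch_mg_per_ml"]),
                    rrs_values=tuple(float(v) for v in sub["rrs"]),
                )
            )
        except (TypeError, ValueError, InputValidationError) as exc:
            raise InputValidationError(f"{path}: mouse {mouse!r} at HDM dose {hdm!r}: {exc}") from None
    return curves


def write_ahr_table(curves: Iterable[AhrCurve], path: str | Path) -> None:
    rows = [
        {
            "mouse_id": c.mouse_id,
            "group": c.group,
            "hdm_dose_ug": c.hdm_dose,
            "mch_mg_per_ml": conc,
            "rrs": rrs,
        }
        for c in curves
        for conc, rrs in zip(c.mch_concentrations, c.rrs_values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def fold_changes_to_frame(results: Iterable[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group,
                "dose_ug": r.dose,
                "analyte": r.analyte,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "fold_change": r.fold_change,
            }
            for r in results
        ]
    )


def fits_to_frame(fits: Iterable[SlopeFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append(
            {
                "group": f.group,
                "analyte": f.analyte,
                "n": f.n,
                "slope": f.slope,
                "intercept": f.intercept,
                "slope_se": f.slope_se,
                "t_stat": f.t_stat,
                "df": f.df,
                "p_value": f.p_value,
                "perfect_fit": f.perfect_fit,
                "inverse_slope": (1.0 / f.slope) if f.slope != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def frame_to_fits(df: pd.DataFrame) -> list[SlopeFit]:
    required = ["group", "analyte", "n", "slope", "intercept", "slope_se", "t_stat", "df", "p_value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputValidationError(f"slope-fit table missing columns {missing}")
    return [
        SlopeFit(
            group=str(r["group"]),
            analyte=str(r["analyte"]),
            n=int(r["n"]),
            slope=float(r["slope"]),
            intercept=float(r["intercept"]),
            slope_se=float(r["slope_se"]),
            t_stat=float(r["t_stat"]),
            df=int(r["df"]),
            p_value=float(r["p_value"]),
            perfect_fit=bool(r.get("perfect_fit", False)),
        )
        for _, r in df.iterrows()
    ]


def scores_to_frame(results: Iterable[ScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "analytes_used": ";".join(r.analytes_used),
                "p_values": ";".join(f"{p:.6g}" for p in r.p_values),
                "score": r.score,
                "alpha": r.alpha,
                "cutoff": r.cutoff,
                "label": r.label,
            }
            for r in results
        ]
    )


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n", encoding="utf-8")


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise InputValidationError(f"{path}: config must be a mapping")
    return cfg
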