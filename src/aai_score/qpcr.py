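"""Comparative C_T (2^-ddCt) relative quantification.

Cycle-threshold (C_T) values from quantitative RT-PCR are converted into
fold-change expression values in three steps:

1. ``delta_ct`` — normalize to an endogenous reference gene (GAPDH by
   default): dCt = mean target C_T − mean reference C_T, within a sample.
2. ``delta_delta_ct`` — subtract the calibrator dCt.  The calibrator here is
   the mean dCt of the PBS-exposed (dose 0) samples of the *same* group, so
   each strain/genotype is expressed relative to its own unexposed controls.
3. ``fold_change`` — 2^(−ddCt).  By construction the calibrator group has an
   expected fold change of 1.

Amplification efficiency is fixed at 2 per cycle; efficiency-corrected
(Pfaffl-style) quantification is out of scope.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .exceptions import InputValidationError, MissingDataError

__all__ = [
    "CtRecord",
    "FoldChangeResult",
    "mean_ct",
    "delta_ct",
    "delta_delta_ct",
    "fold_change",
    "quantify_table",
    "DEFAULT_REFERENCE_GENE",
]

DEFAULT_REFERENCE_GENE = "GAPDH"


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InputValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: replicate C_T values for one sample x gene.

    ``dose`` is the allergen dose in ug; dose 0 denotes the PBS calibrator
    exposure.  Replicate wells (the assay is run in triplicate) are kept as a
    tuple and averaged before any subtraction.
    """

    sample_id: str
    group: str
    dose: float
    gene: str
    ct_replicates: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ct_replicates", tuple(float(v) for v in self.ct_replicates))
        if len(self.ct_replicates) == 0:
            raise InputValidationError(
                f"sample {self.sample_id!r} gene {self.gene!r}: ct_replicates is empty"
            )
        for v in self.ct_replicates:
            if not math.isfinite(v) or v <= 0:
                raise InputValidationError(
                    f"sample {self.sample_id!r} gene {self.gene!r}: "
                    f"C_T replicate {v!r} is not a finite positive cycle count"
                )
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InputValidationError(
                f"sample {self.sample_id!r}: dose must be a finite non-negative ug amount"
            )


@dataclass(frozen=True)
class FoldChangeResult:
    """Relative expression of one target gene in one sample.

    ``fold_change`` equals 2^(−delta_delta_ct) exactly; it is dimensionless
    and strictly positive (1 means expression equal to the calibrator).
    """

    sample_id: str
    group: str
    dose: float
    analyte: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def mean_ct(ct_replicates: Sequence[float]) -> float:
    """Arithmetic mean of replicate C_T values (cycles)."""
    values = [float(v) for v in ct_replicates]
    if not values:
        raise InputValidationError("ct_replicates is empty")
    for v in values:
        if not math.isfinite(v):
            raise InputValidationError(f"non-finite C_T replicate {v!r}")
    return sum(values) / len(values)


def delta_ct(target_ct: float, reference_ct: float) -> float:
    """dCt = target C_T − reference-gene C_T (cycles), within one sample."""
    return _require_finite("target_ct", target_ct) - _require_finite("reference_ct", reference_ct)


def delta_delta_ct(sample_dct: float, calibrator_dct: float) -> float:
    """ddCt = sample dCt − calibrator dCt (cycles)."""
    return _require_finite("sample_dct", sample_dct) - _require_finite(
        "calibrator_dct", calibrator_dct
    )


def fold_change(ddct: float) -> float:
    """Relative expression 2^(−ddCt); 1 at the calibrator, >1 means induction."""
    return 2.0 ** (-_require_finite("ddct", ddct))


def quantify_table(
    records: Iterable[CtRecord],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator_dose: float = 0.0,
) -> list[FoldChangeResult]:
    """Run the comparative-C_T method over a table of C_T records.

    For every sample, each target gene's dCt is taken against the
    ``reference_gene`` within that sample; the calibrator dCt for a
    (group, gene) pair is the mean dCt over all samples of that group at
    ``calibrator_dose`` (the PBS controls), so the calibrator group's mean
    fold change is 1 in expectation.

    Records sharing (sample_id, group, dose, gene) are pooled into one
    replicate set.  Results are ordered by (group, dose, sample, analyte).
    """
    pooled: dict[tuple[str, str, float, str], list[float]] = defaultdict(list)
    for rec in records:
        pooled[(rec.sample_id, rec.group, rec.dose, rec.gene)].extend(rec.ct_replicates)
    if not pooled:
        raise InputValidationError("no C_T records supplied")

    # sample -> mean reference C_T; sample -> {gene: mean C_T}
    samples: dict[tuple[str, str, float], dict[str, float]] = defaultdict(dict)
    for (sample, group, dose, gene), cts in pooled.items():
        samples[(sample, group, dose)][gene] = mean_ct(cts)

    dct_by_sample: dict[tuple[str, str, float], dict[str, float]] = {}
    for key, genes in samples.items():
        sample, group, dose = key
        if reference_gene not in genes:
            raise MissingDataError(
                f"sample {sample!r} has no record for reference gene {reference_gene!r}"
            )
        ref = genes[reference_gene]
        dct_by_sample[key] = {
            gene: delta_ct(ct, ref) for gene, ct in genes.items() if gene != reference_gene
        }

    # calibrator dCt per (group, gene): mean over the group's calibrator-dose samples
    calib_values: dict[tuple[str, str], list[float]] = defaultdict(list)
    groups = {key[1] for key in samples}
    for (sample, group, dose), dcts in dct_by_sample.items():
        if dose == calibrator_dose:
            for gene, v in dcts.items():
                calib_values[(group, gene)].append(v)
    for group in sorted(groups):
        if not any(g == group for g, _ in calib_values):
            raise MissingDataError(
                f"group {group!r} has no sample at calibrator dose {calibrator_dose!r}"
            )

    results: list[FoldChangeResult] = []
    for (sample, group, dose), dcts in sorted(dct_by_sample.items(), key=lambda kv: (kv[0][1], kv[0][2], kv[0][0])):
        for gene in sorted(dcts):
            if (group, gene) not in calib_values:
                raise MissingDataError(
                    f"group {group!r} gene {gene!r}: no calibrator-dose samples measured this gene"
                )
            cal = calib_values[(group, gene)]
            calibrator_dct = sum(cal) / len(cal)
            ddct = delta_delta_ct(dcts[gene], calibrator_dct)
            results.append(
                FoldChangeResult(
                    sample_id=sample,
                    group=group,
                    dose=dose,
                    analyte=gene,
                    delta_ct=dcts[gene],
                    delta_delta_ct=ddct,
                    fold_change=fold_change(ddct),
                )
            )
    return results
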