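"""Synthetic allergen dose-response cohorts.

Generates mouse cohorts with the statistical structure the scoring pipeline
assumes: groups (strain x genotype) exposed to house-dust-mite doses
{0 (PBS), 5, 25, 100} ug, each mouse yielding a PBS-normalized fold-change
response per analyte with mean ``1 + beta * dose`` (PBS expectation 1) and
either multiplicative log-normal noise (default; fold-change data are
positive and log-plotted) or additive gaussian noise (handy when a simple
exact oracle is wanted).  The same cohorts can be emitted as raw qPCR C_T
tables (so the comparative-C_T stage is exercised end to end) and as
airway-resistance curves with a saturating methacholine response.

All randomness flows through explicit seeds; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .ahr import AhrCurve
from .dose_response import ResponseRecord
from .exceptions import InputValidationError
from .qpcr import DEFAULT_REFERENCE_GENE, CtRecord

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "simulate_responses",
    "simulate_ct",
    "simulate_ahr",
    "reference_scenario",
]

#: floor applied to the (pre-noise) mean response so values stay positive
MEAN_FLOOR = 1e-6

DEFAULT_DOSES: tuple[float, ...] = (0.0, 5.0, 25.0, 100.0)
DEFAULT_ANALYTE_PANEL: tuple[str, ...] = ("IL-4", "IL-13", "CCL7", "CCL11", "IFN-g")
DEFAULT_MCH: tuple[float, ...] = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class GroupSpec:
    """True effect sizes for one strain/genotype group.

    ``slopes`` maps analyte -> true dose slope beta (fold change per ug of
    allergen); ``ahr_gain`` is the saturating-response amplitude of the
    airway-resistance curve (cm H2O/mL) and ``ahr_baseline`` its resistance
    at zero methacholine.
    """

    name: str
    slopes: Mapping[str, float]
    ahr_gain: float = 1.0
    ahr_baseline: float = 0.6


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``sigma`` is the noise scale: SD of log2(value) for the multiplicative
    log-normal model, SD in fold units for the additive gaussian model.
    """

    groups: tuple[GroupSpec, ...]
    doses: tuple[float, ...] = DEFAULT_DOSES
    n_per_dose: int = 5
    analytes: tuple[str, ...] = DEFAULT_ANALYTE_PANEL
    noise_model: str = "lognormal"  # "lognormal" | "additive"
    sigma: float = 0.35
    mean_shape: str = "linear"  # "linear" | "power" (convex stress-test)
    power_exponent: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        problems = []
        if not self.groups:
            problems.append("groups must be non-empty")
        if self.n_per_dose < 1:
            problems.append(f"n_per_dose must be >= 1, got {self.n_per_dose}")
        if self.sigma < 0:
            problems.append(f"sigma must be >= 0, got {self.sigma}")
        if any(d < 0 or not math.isfinite(d) for d in self.doses):
            problems.append(f"doses must be finite and non-negative: {self.doses}")
        if len(set(self.doses)) != len(self.doses):
            problems.append(f"doses must be distinct: {self.doses}")
        if self.noise_model not in ("lognormal", "additive"):
            problems.append(f"unknown noise_model {self.noise_model!r}")
        if self.mean_shape not in ("linear", "power"):
            problems.append(f"unknown mean_shape {self.mean_shape!r}")
        for g in self.groups:
            missing = [a for a in self.analytes if a not in g.slopes]
            if missing:
                problems.append(f"group {g.name!r} lacks slopes for {missing}")
        if problems:
            raise InputValidationError("invalid CohortSpec: " + "; ".join(problems))


def _rng(spec: CohortSpec, seed: int | None, stream: int) -> np.random.Generator:
    s = seed if seed is not None else spec.seed
    if s is None:
        return np.random.default_rng()
    return np.random.default_rng([int(s), stream])


def _mean_response(spec: CohortSpec, beta: float, dose: float) -> float:
    if spec.mean_shape == "power":
        return max(MEAN_FLOOR, 1.0 + beta * dose**spec.power_exponent)
    return max(MEAN_FLOOR, 1.0 + beta * dose)


def simulate_responses(spec: CohortSpec, seed: int | None = None) -> list[ResponseRecord]:
    """Draw one cohort of PBS-normalized fold-change responses.

    Multiplicative model: value = mean * 2**(sigma * z); additive model:
    value = max(MEAN_FLOOR, mean + sigma * z), z ~ N(0, 1).  PBS (dose 0)
    mice have mean exactly 1.
    """
    rng = _rng(spec, seed, stream=0)
    records: list[ResponseRecord] = []
    for g in spec.groups:
        for dose in spec.doses:
            for i in range(spec.n_per_dose):
                mouse = f"{g.name}-d{dose:g}-m{i + 1}"
                for analyte in spec.analytes:
                    mean = _mean_response(spec, g.slopes[analyte], dose)
                    z = rng.standard_normal()
                    if spec.noise_model == "lognormal":
                        value = mean * 2.0 ** (spec.sigma * z)
                    else:
                        value = max(MEAN_FLOOR, mean + spec.sigma * z)
                    records.append(
                        ResponseRecord(
                            mouse_id=mouse, group=g.name, dose=dose, analyte=analyte, value=value
                        )
                    )
    return records


def simulate_ct(
    spec: CohortSpec,
    reference_ct: float = 20.0,
    seed: int | None = None,
    base_delta_ct: Mapping[str, float] | None = None,
    jitter_sd: float = 0.0,
    replicates: int = 3,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> list[CtRecord]:
    """Encode a simulated cohort as raw qPCR cycle thresholds.

    Draws the same fold-change responses as :func:`simulate_responses` (same
    seed => same cohort) and encodes each as

        target C_T = sample reference C_T + base dCt(analyte) − log2(fold)

    so that :func:`~aai_score.qpcr.quantify_table` recovers the simulated
    fold changes exactly when the cohort is noiseless (all PBS folds are then
    exactly 1, pinning the calibrator dCt at the base dCt).  ``jitter_sd``
    adds per-sample gaussian shifts to the reference C_T — these cancel in
    dCt and so leave the recovered folds untouched.
    """
    if not math.isfinite(reference_ct):
        raise InputValidationError(f"reference_ct must be finite, got {reference_ct!r}")
    if jitter_sd < 0:
        raise InputValidationError(f"jitter_sd must be >= 0, got {jitter_sd!r}")
    if replicates < 1:
        raise InputValidationError(f"replicates must be >= 1, got {replicates!r}")
    if base_delta_ct is None:
        base_delta_ct = {a: 5.0 for a in spec.analytes}
    missing = [a for a in spec.analytes if a not in base_delta_ct]
    if missing:
        raise InputValidationError(f"base_delta_ct lacks analytes {missing}")

    responses = simulate_responses(spec, seed=seed)
    rng = _rng(spec, seed, stream=1)
    by_sample: dict[tuple[str, str, float], dict[str, float]] = {}
    for r in responses:
        by_sample.setdefault((r.mouse_id, r.group, r.dose), {})[r.analyte] = r.value

    records: list[CtRecord] = []
    for (mouse, group, dose), folds in by_sample.items():
        ref_ct = reference_ct + (jitter_sd * rng.standard_normal() if jitter_sd else 0.0)
        records.append(
            CtRecord(
                sample_id=mouse,
                group=group,
                dose=dose,
                gene=reference_gene,
                ct_replicates=(ref_ct,) * replicates,
            )
        )
        for analyte in spec.analytes:
            tct = ref_ct + float(base_delta_ct[analyte]) - math.log2(folds[analyte])
            records.append(
                CtRecord(
                    sample_id=mouse,
                    group=group,
                    dose=dose,
                    gene=analyte,
                    ct_replicates=(tct,) * replicates,
                )
            )
    return records


def simulate_ahr(
    spec: CohortSpec,
    seed: int | None = None,
    mch_concentrations: tuple[float, ...] = DEFAULT_MCH,
    c50: float = 25.0,
    rrs_sigma: float = 0.15,
    hdm_dose_factor: float = 0.005,
) -> list[AhrCurve]:
    """Airway-resistance curves: baseline + gain * c/(c + c50) + noise.

    The group's ``ahr_gain`` is scaled by ``1 + hdm_dose_factor * hdm_dose``,
    giving the limited allergen-dose dependence seen in this readout.  Rrs
    values are clipped at 0 (resistance cannot be negative).
    """
    rng = _rng(spec, seed, stream=2)
    c = np.asarray(mch_concentrations, dtype=float)
    curves: list[AhrCurve] = []
    for g in spec.groups:
        for dose in spec.doses:
            gain = g.ahr_gain * (1.0 + hdm_dose_factor * dose)
            for i in range(spec.n_per_dose):
                mouse = f"{g.name}-d{dose:g}-m{i + 1}"
                rrs = g.ahr_baseline + gain * c / (c + c50) + rrs_sigma * rng.standard_normal(c.size)
                rrs = np.clip(rrs, 0.0, None)
                curves.append(
                    AhrCurve(
                        mouse_id=mouse,
                        group=g.name,
                        hdm_dose=dose,
                        mch_concentrations=tuple(c),
                        rrs_values=tuple(float(v) for v in rrs),
                    )
                )
    return curves


def reference_scenario(n_per_dose: int = 5, sigma: float = 0.35, seed: int | None = None) -> CohortSpec:
    """Four-group scenario mirroring the qualitative strain/knockout contrasts.

    Groups (true slopes in fold change per ug, per analyte):

    * ``BALBc`` — strong responder: robust dose-dependent Th2 response.
    * ``B6`` — moderate responder: clearly dose dependent but several-fold
      weaker, giving a higher (less susceptible) score.
    * ``BALBc-ItkKO`` — small but nonzero slopes: reduced susceptibility,
      still not resistant.
    * ``B6-ItkKO`` — zero slopes on every analyte: the resistant group.

    IFN-gamma slopes are kept near zero throughout (a Th2-skewed response);
    it is excluded from the default score anyway.  With the default noise
    (sigma = 0.35 on log2 fold change, i.e. roughly a 27% geometric CV —
    ordinary inter-mouse variability for lung qPCR panels) and 5 mice per
    dose, the full pipeline labels the three responder groups susceptible
    and the zero-slope group resistant, with scores ordered
    BALBc < B6 < BALBc-ItkKO.
    """
    groups = (
        GroupSpec(
            name="BALBc",
            slopes={"IL-4": 0.12, "IL-13": 0.10, "CCL7": 0.08, "CCL11": 0.05, "IFN-g": 0.01},
            ahr_gain=3.0,
        ),
        GroupSpec(
            name="B6",
            slopes={"IL-4": 0.025, "IL-13": 0.02, "CCL7": 0.018, "CCL11": 0.012, "IFN-g": 0.004},
            ahr_gain=2.0,
        ),
        GroupSpec(
            name="BALBc-ItkKO",
            slopes={"IL-4": 0.008, "IL-13": 0.010, "CCL7": 0.008, "CCL11": 0.006, "IFN-g": 0.0},
            ahr_gain=1.0,
        ),
        GroupSpec(
            name="B6-ItkKO",
            slopes={"IL-4": 0.0, "IL-13": 0.0, "CCL7": 0.0, "CCL11": 0.0, "IFN-g": 0.0},
            ahr_gain=0.5,
        ),
    )
    return CohortSpec(groups=groups, n_per_dose=n_per_dose, sigma=sigma, seed=seed)
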