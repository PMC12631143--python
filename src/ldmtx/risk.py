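"""CKD risk-threshold calculus and dose optimization.

The adverse-reaction Cmax cutoff of 0.16 µmol/L, established for weekly oral
methotrexate at the baseline dose m0 = 2.3 mg in adults with normal renal
function, is scaled linearly in the administered dose and in renal function:

    threshold(M, eGFR) = 0.16 * (M / m0) * (eGFR / eGFR_norm)   [µmol/L]

``eGFR_norm`` defaults to 90 mL/min/1.73 m2, the normalization that
reproduces the published threshold table cell-for-cell; the healthy-reference
value 106.78 is available as an alternative but does not reproduce the table
(see docs/methods.md).

Regimen assessment simulates a virtual CKD population with the PBPK model
and compares each individual's first-dose Cmax against the threshold at that
individual's own eGFR; the verdict follows the median individual (verdict
"exceeds" when more than half the population exceeds).

Dose optimization anchors the risk bound to the *prescribed* regimen: the
patient's threshold is fixed at threshold(initial dose, anchor eGFR), and the
dose is stepped down in 2.5 mg tablets until the simulated Cmax of the
reduced dose falls below that bound.  Because the PBPK model is dose-linear,
re-deriving the threshold from the reduced dose itself would make the
comparison dose-free and no reduction could ever change the verdict; fixing
the bound at the prescribed regimen is the reading under which tablet
reductions are meaningful.  The anchor individual is the reference adult at
the stage's midpoint eGFR (the stage-typical patient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pbpk
from .config import (
    BASELINE_DOSE_MG,
    CMAX_CUTOFF_UMOL_L,
    EGFR_NORM_DEFAULT,
    LABEL_DOSES_MG,
    STAGE_EGFR_BOUNDS,
    TABLET_MG,
    THRESHOLD_TABLE_ANCHORS,
)

__all__ = [
    "compute_threshold",
    "generate_threshold_table",
    "RegimenAssessment",
    "assess_regimen",
    "OptimizedRegimen",
    "optimize_dose",
]


def compute_threshold(dose_mg: float, egfr: float,
                      m0_mg: float = BASELINE_DOSE_MG,
                      c0: float = CMAX_CUTOFF_UMOL_L,
                      egfr_norm: float = EGFR_NORM_DEFAULT) -> float:
    """Cmax risk threshold (µmol/L) for a dose at a given renal function.

    Linear in both the dose and the eGFR; full precision is returned (table
    rendering rounds to 3 decimals separately).
    """
    for name, val in (("dose_mg", dose_mg), ("egfr", egfr), ("m0_mg", m0_mg),
                      ("c0", c0), ("egfr_norm", egfr_norm)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    return c0 * (dose_mg / m0_mg) * (egfr / egfr_norm)


def generate_threshold_table(doses=LABEL_DOSES_MG,
                             stage_egfr_pairs=THRESHOLD_TABLE_ANCHORS,
                             m0_mg: float = BASELINE_DOSE_MG,
                             c0: float = CMAX_CUTOFF_UMOL_L,
                             egfr_norm: float = EGFR_NORM_DEFAULT,
                             decimals: int = 3) -> pd.DataFrame:
    """Threshold grid over the label regimens and eGFR anchor rows.

    One row per (stage, eGFR) anchor, one column per dose, each cell the
    threshold rounded to ``decimals``.
    """
    rows = []
    for stage, egfr in stage_egfr_pairs:
        row = {"stage": stage, "egfr": egfr}
        for dose in doses:
            row[f"{dose:g} mg"] = round(
                compute_threshold(dose, egfr, m0_mg, c0, egfr_norm), decimals)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RegimenAssessment:
    """Population verdict for one (stage, dose) regimen."""

    stage: str
    dose_mg: float
    threshold_dose_mg: float
    n: int
    cmax_median: float
    cmax_p5: float
    cmax_p95: float
    threshold_median: float
    exceedance_fraction: float
    verdict: str  # "below" | "exceeds"


def assess_regimen(params: pbpk.PBPKParameters, stage: str, dose_mg: float,
                   n: int = 200, seed: int = 0,
                   egfr_norm: float = EGFR_NORM_DEFAULT,
                   threshold_dose_mg: float | None = None,
                   exceed_cutoff: float = 0.5,
                   dt: float = 0.1) -> RegimenAssessment:
    """Simulate a virtual stage population and compare Cmax to thresholds.

    Each individual's first-dose Cmax is compared with the threshold at that
    individual's own eGFR; ``threshold_dose_mg`` (default: the simulated
    dose) sets the regimen the threshold is derived from, which matters for
    optimization.  Verdict is "exceeds" when the exceedance fraction passes
    ``exceed_cutoff`` (default: the median individual).
    """
    if stage not in STAGE_EGFR_BOUNDS:
        raise ValueError(f"unknown stage {stage!r}")
    thr_dose = dose_mg if threshold_dose_mg is None else threshold_dose_mg
    pop = pbpk.generate_virtual_population(stage, n, seed)
    regimen = pbpk.Regimen(dose_mg=dose_mg)
    cmax = np.empty(n)
    thr = np.empty(n)
    for i, ind in enumerate(pop):
        cmax[i] = pbpk.simulate_profile(params, ind, regimen, dt=dt).cmax
        thr[i] = compute_threshold(thr_dose, ind.egfr, egfr_norm=egfr_norm)
    exceed = float(np.mean(cmax > thr))
    return RegimenAssessment(
        stage=stage, dose_mg=dose_mg, threshold_dose_mg=thr_dose, n=n,
        cmax_median=float(np.median(cmax)),
        cmax_p5=float(np.percentile(cmax, 5)),
        cmax_p95=float(np.percentile(cmax, 95)),
        threshold_median=float(np.median(thr)),
        exceedance_fraction=exceed,
        verdict="exceeds" if exceed > exceed_cutoff else "below",
    )


@dataclass
class OptimizedRegimen:
    """Tablet-quantized dose reduction for one stage and initial regimen."""

    stage: str
    initial_dose_mg: float
    optimized_dose_mg: float
    reduction_mg: float
    reduction_tablets: int
    anchor_egfr: float
    threshold_umol_L: float
    cmax_at_optimized: float


def _stage_anchor_egfr(stage: str, anchor: str) -> float:
    lo, hi = STAGE_EGFR_BOUNDS[stage]
    if anchor == "midpoint":
        return 0.5 * (lo + hi)
    if anchor == "lower":
        return lo
    if anchor == "upper":
        return hi
    raise ValueError(f"unknown anchor {anchor!r}")


def optimize_dose(params: pbpk.PBPKParameters, stage: str,
                  initial_dose_mg: float, step: float = TABLET_MG,
                  egfr_norm: float = EGFR_NORM_DEFAULT,
                  anchor: str = "midpoint",
                  dt: float = 0.05) -> OptimizedRegimen:
    """Largest tablet-multiple dose whose Cmax stays below the prescribed
    regimen's risk threshold at the stage-typical eGFR.

    Steps down from ``initial_dose_mg`` in ``step`` (tablet) decrements; the
    threshold stays fixed at the initial regimen (see module docstring).
    Raises ValueError when even one tablet exceeds the bound.
    """
    if stage not in STAGE_EGFR_BOUNDS:
        raise ValueError(f"unknown stage {stage!r}")
    n_steps = initial_dose_mg / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"initial dose {initial_dose_mg} is not a multiple "
                         f"of the {step} mg tablet")
    anchor_egfr = _stage_anchor_egfr(stage, anchor)
    ind = pbpk.reference_individual(egfr=anchor_egfr, stage=stage)
    threshold = compute_threshold(initial_dose_mg, anchor_egfr,
                                  egfr_norm=egfr_norm)
    candidates = [round(k * step, 10)
                  for k in range(int(round(n_steps)), 0, -1)]
    for dose in candidates:
        cmax = pbpk.simulate_profile(params, ind,
                                     pbpk.Regimen(dose_mg=dose), dt=dt).cmax
        if cmax <= threshold + 1e-12:
            reduction = initial_dose_mg - dose
            return OptimizedRegimen(
                stage=stage, initial_dose_mg=initial_dose_mg,
                optimized_dose_mg=dose, reduction_mg=reduction,
                reduction_tablets=int(round(reduction / step)),
                anchor_egfr=anchor_egfr, threshold_umol_L=threshold,
                cmax_at_optimized=cmax)
    raise ValueError(
        f"no dose >= one {step} mg tablet keeps Cmax below the "
        f"{threshold:.3f} µmol/L bound for {stage} "
        f"(minimum-dose failure)")
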