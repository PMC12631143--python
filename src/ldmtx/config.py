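"""Shared constants and pipeline configuration.

Every literature-derived constant used by the pipeline lives here so it has
exactly one home: the adverse-reaction Cmax cutoff and its baseline dose, the
reference healthy adult and their eGFR, CKD stage bounds, the weekly label
regimens, the three-way disproportionality cutoffs, and the reference
dose->Cmax spline coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# ---------------------------------------------------------------------------
# Exposure anchor: first-dose Cmax cutoff for adverse-reaction risk in adults
# with normal renal function, and the baseline weekly oral dose paired with it.
CMAX_CUTOFF_UMOL_L = 0.16
BASELINE_DOSE_MG = 2.3

# eGFR normalization used in the risk-threshold scaling.  90 mL/min/1.73 m2
# reproduces the published threshold table cell-for-cell; the healthy-reference
# eGFR (106.78) is retained as an alternative normalization but does not
# reproduce the table (see docs/methods.md).
EGFR_NORM_DEFAULT = 90.0
EGFR_REF = 106.78  # virtual healthy European male, 30 y / 176 cm / 73 kg

REFERENCE_AGE_Y = 30.0
REFERENCE_HEIGHT_CM = 176.0
REFERENCE_WEIGHT_KG = 73.0

MTX_MOLECULAR_WEIGHT = 454.44  # g/mol

# Weekly oral label regimens (mg) and the tablet strength used for dose steps.
LABEL_DOSES_MG = (7.5, 10.0, 15.0, 20.0)
TABLET_MG = 2.5
WEEKLY_INTERVAL_H = 168.0

# CKD stage bounds on eGFR (mL/min/1.73 m2).  Stage 1 is simulated between the
# 90 boundary and the healthy reference value.
STAGE_EGFR_BOUNDS: dict[str, tuple[float, float]] = {
    "healthy": (EGFR_REF, EGFR_REF),
    "CKD1": (90.0, EGFR_REF),
    "CKD2": (60.0, 89.0),
    "CKD3a": (45.0, 59.0),
    "CKD3b": (30.0, 44.0),
}
CKD_STAGES = ("CKD1", "CKD2", "CKD3a", "CKD3b")

# Three-way disproportionality signal rule: a PT is a signal only if the
# report count, PRR + chi-square, ROR CI lower bound and IC025 all pass.
MIN_REPORTS = 3
PRR_MIN = 2.0
CHI2_MIN = 4.0
ROR_CI_LOW_MIN = 1.0
IC025_MIN = 0.0

# Reference restricted-cubic-spline dose->Cmax model for healthy adults
# (weekly oral methotrexate): beta0..beta3 and the four knots (mg).
RCS_BETAS = (0.0636, 0.0139, 0.0542, -0.0912)
RCS_KNOTS = (5.0, 7.5, 15.0, 22.5)
RCS_KNOT_QUANTILES = (0.05, 0.275, 0.725, 0.95)

# eGFR anchor rows of the published threshold table: (stage, eGFR).
THRESHOLD_TABLE_ANCHORS = (
    ("CKD1", 90.0),
    ("CKD2", 89.0),
    ("CKD2", 60.0),
    ("CKD3a", 59.0),
    ("CKD3a", 45.0),
    ("CKD3b", 44.0),
    ("CKD3b", 30.0),
)


@dataclass
class PipelineConfig:
    """End-to-end run configuration with literature defaults.

    All constants default to the published values; everything is overridable
    from a YAML file (see :meth:`from_yaml`).
    """

    seed: int = 1
    drug: str = "methotrexate"
    renal_only: bool = True

    # synthetic FAERS corpus
    n_cases: int = 8000
    renal_fraction: float = 0.30
    duplicate_fraction: float = 0.05

    # signal rule
    min_reports: int = MIN_REPORTS
    prr_min: float = PRR_MIN
    chi2_min: float = CHI2_MIN
    ror_ci_low_min: float = ROR_CI_LOW_MIN
    ic025_min: float = IC025_MIN

    # risk calculus
    c0_umol_L: float = CMAX_CUTOFF_UMOL_L
    m0_mg: float = BASELINE_DOSE_MG
    egfr_norm: float = EGFR_NORM_DEFAULT
    label_doses_mg: tuple = LABEL_DOSES_MG
    tablet_mg: float = TABLET_MG

    # RCS synthesis / fit
    rcs_noise_sd: float = 0.01
    rcs_n_per_dose: int = 30

    # PBPK calibration
    calib_noise_cv: float = 0.15
    calib_doses_mg: tuple = (7.5, 15.0)
    calib_n_subjects: int = 6
    calib_n_starts: int = 2

    # population assessment
    assess_n: int = 50
    pbpk_params_file: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["label_doses_mg"] = list(self.label_doses_mg)
        data["calib_doses_mg"] = list(self.calib_doses_mg)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("label_doses_mg", "calib_doses_mg"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
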