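"""Minimal mechanistic PBPK model of oral methotrexate with CKD scaling.

Model structure
---------------
Three mass states (amounts, µmol): gut depot, central (plasma + rapidly
equilibrating tissue) and peripheral compartment, plus two bookkeeping states
(cumulative eliminated amount, unabsorbed first-pass loss) so mass balance can
be audited at every grid time.  First-order absorption with bioavailability F;
two-compartment linear distribution; elimination from the central compartment
through four explicit routes:

* renal filtration   ``fu * GFR_abs``  (absolute GFR from eGFR via body
  surface area),
* renal tubular secretion ``CL_sec`` — a lumped linear clearance standing for
  the basolateral uptake (OAT3, RFC1) -> apical efflux (MRP4, BCRP) chain,
* hepatic metabolic clearance ``CL_hep``,
* biliary clearance ``CL_bile``.

Chronic kidney disease is mapped in with the intact-nephron scaling: the
transporter concentration ratio equals eGFR_CKD / eGFR_ref, so the secretory
clearance scales proportionally with eGFR, filtration scales directly through
GFR, and the hepatic/biliary routes are left unscaled (metabolic
compensation).  Secretion is modelled linear because low-dose methotrexate
plasma concentrations (<= ~1.4 µmol/L) sit far below the reported transporter
IC50s (e.g. OAT3 61.5 µM).

The system is linear, so propagation uses the matrix exponential over each
grid step — exact for the stated model, unconditionally stable, and
deterministic.  The closed-form eigendecomposition solution is used as an
independent oracle in the test suite, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .config import (
    EGFR_REF,
    MTX_MOLECULAR_WEIGHT,
    REFERENCE_AGE_Y,
    REFERENCE_HEIGHT_CM,
    REFERENCE_WEIGHT_KG,
    STAGE_EGFR_BOUNDS,
    WEEKLY_INTERVAL_H,
)

__all__ = [
    "PBPKParameters",
    "Individual",
    "Regimen",
    "ConcentrationProfile",
    "EvaluationMetrics",
    "bsa_dubois",
    "gfr_absolute_L_h",
    "default_parameters",
    "reference_individual",
    "scale_to_ckd",
    "simulate_profile",
    "generate_virtual_population",
    "calibrate_healthy",
    "evaluate_model",
    "sensitivity_analysis",
    "read_parameters",
    "write_parameters",
]


def bsa_dubois(weight_kg: float, height_cm: float) -> float:
    """DuBois body surface area (m2)."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


BSA_REF = bsa_dubois(REFERENCE_WEIGHT_KG, REFERENCE_HEIGHT_CM)


def gfr_absolute_L_h(egfr_ml_min_173: float, bsa_m2: float) -> float:
    """Convert a BSA-normalized eGFR (mL/min/1.73 m2) to absolute GFR in L/h."""
    return egfr_ml_min_173 * (bsa_m2 / 1.73) * 60.0 / 1000.0


@dataclass(frozen=True)
class PBPKParameters:
    """Compound and reference-physiology constants.

    Clearances are for the healthy reference adult (30 y, 176 cm, 73 kg,
    eGFR 106.78 mL/min/1.73 m2); they are rescaled per individual by body
    size and, for the renal routes, by renal function.

    The default central volume is calibrated so that a single 2.3 mg oral
    dose in the reference adult peaks at the 0.16 µmol/L exposure anchor;
    the clearance split honours the urinary-excretion constraints (renal
    share of total clearance > 0.8; secretion 60–80% of renal clearance).
    """

    molecular_weight: float = MTX_MOLECULAR_WEIGHT  # g/mol
    fu: float = 0.54          # fraction unbound in plasma
    ka: float = 1.5           # 1/h first-order absorption
    F: float = 0.85           # oral bioavailability (low-dose regimens)
    Vc: float = 9.9           # L central volume (reference body)
    Vp: float = 20.0          # L peripheral volume
    Q: float = 4.0            # L/h inter-compartment clearance
    CL_sec: float = 5.8       # L/h lumped tubular secretion (OAT3/RFC1 -> MRP4/BCRP)
    CL_hep: float = 1.00      # L/h hepatic metabolic clearance
    CL_bile: float = 0.40     # L/h biliary clearance
    GFR_ref: float = EGFR_REF  # mL/min/1.73 m2

    # --- derived reference-quantities -------------------------------------
    @property
    def gfr_abs_ref_L_h(self) -> float:
        return gfr_absolute_L_h(self.GFR_ref, BSA_REF)

    @property
    def cl_filtration_ref(self) -> float:
        return self.fu * self.gfr_abs_ref_L_h

    @property
    def cl_renal_ref(self) -> float:
        return self.cl_filtration_ref + self.CL_sec

    @property
    def cl_total_ref(self) -> float:
        return self.cl_renal_ref + self.CL_hep + self.CL_bile

    @property
    def renal_share(self) -> float:
        return self.cl_renal_ref / self.cl_total_ref

    @property
    def secretion_share(self) -> float:
        return self.CL_sec / self.cl_renal_ref

    def validate(self) -> None:
        """Raise ValueError if any physiological invariant is violated."""
        positive = ("molecular_weight", "ka", "Vc", "Vp", "Q", "CL_sec",
                    "CL_hep", "CL_bile", "GFR_ref")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("fu", "F"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {getattr(self, name)}")
        if not self.renal_share > 0.8:
            raise ValueError(
                f"renal share of total clearance must exceed 0.8 "
                f"(>80% of methotrexate is excreted unchanged in urine); "
                f"got {self.renal_share:.3f}")
        if not 0.6 <= self.secretion_share <= 0.8:
            raise ValueError(
                f"tubular secretion must account for 60-80% of renal "
                f"clearance; got {self.secretion_share:.3f}")


def default_parameters() -> PBPKParameters:
    """Calibrated healthy-reference parameter set (see class docstring)."""
    return PBPKParameters()


@dataclass(frozen=True)
class Individual:
    """A (virtual) subject: anthropometrics, renal function and CKD stage."""

    age_years: float
    height_cm: float
    weight_kg: float
    egfr: float  # mL/min/1.73 m2
    stage: str = "healthy"

    def __post_init__(self):
        if self.egfr <= 0:
            raise ValueError("egfr must be > 0")
        if self.stage not in STAGE_EGFR_BOUNDS:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def bsa(self) -> float:
        return bsa_dubois(self.weight_kg, self.height_cm)

    @property
    def transporter_ratio(self) -> float:
        """Intact-nephron transporter scaling: eGFR_CKD / eGFR_ref."""
        return self.egfr / EGFR_REF


def reference_individual(egfr: float = EGFR_REF, stage: str = "healthy") -> Individual:
    return Individual(REFERENCE_AGE_Y, REFERENCE_HEIGHT_CM, REFERENCE_WEIGHT_KG,
                      egfr, stage)


@dataclass(frozen=True)
class Regimen:
    """Oral dosing schedule; weekly interval by default."""

    dose_mg: float
    interval_h: float = WEEKLY_INTERVAL_H
    n_doses: int = 1
    route: str = "oral"

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.route != "oral":
            raise ValueError("only oral dosing is modelled")


@dataclass
class ConcentrationProfile:
    """Simulated (or observed) concentration-time series.

    ``amounts`` columns: gut, central, peripheral, eliminated, unabsorbed
    (µmol); ``administered_umol`` is the cumulative dosed amount at each grid
    time, so mass balance is checkable after the fact.
    """

    times_h: np.ndarray
    conc_umol_L: np.ndarray
    amounts: np.ndarray | None = None
    administered_umol: np.ndarray | None = None

    @property
    def cmax(self) -> float:
        return float(np.max(self.conc_umol_L))

    @property
    def tmax(self) -> float:
        return float(self.times_h[int(np.argmax(self.conc_umol_L))])

    @property
    def auc_last(self) -> float:
        """Linear trapezoid over [0, t_last] (µmol·h/L)."""
        return float(np.trapezoid(self.conc_umol_L, self.times_h))

    def mass_balance_error(self) -> float:
        """Max relative deviation of total accounted mass from dosed mass."""
        if self.amounts is None or self.administered_umol is None:
            raise ValueError("profile carries no amount bookkeeping")
        total = self.amounts.sum(axis=1)
        dosed = self.administered_umol
        scale = max(float(dosed[-1]), 1e-12)
        return float(np.max(np.abs(total - dosed)) / scale)


def scale_to_ckd(params: PBPKParameters, individual: Individual,
                 hepatic_multiplier: float = 1.0) -> dict[str, float]:
    """Effective clearances and volumes for one individual.

    Filtration follows the individual's absolute GFR (fu × GFR_abs);
    secretion scales with body surface area and with the intact-nephron
    transporter ratio; hepatic and biliary clearances scale with body surface
    area only (no renal-function scaling: metabolic compensation retained,
    ``hepatic_multiplier`` exposes a sensitivity dial).  Volumes scale with
    body weight.
    """
    bsa_ratio = individual.bsa / BSA_REF
    size_ratio = individual.weight_kg / REFERENCE_WEIGHT_KG
    gfr_abs = gfr_absolute_L_h(individual.egfr, individual.bsa)
    cl_fil = params.fu * gfr_abs
    cl_sec = params.CL_sec * bsa_ratio * individual.transporter_ratio
    cl_hep = params.CL_hep * bsa_ratio * hepatic_multiplier
    cl_bile = params.CL_bile * bsa_ratio * hepatic_multiplier
    return {
        "GFR_abs_L_h": gfr_abs,
        "CL_filtration": cl_fil,
        "CL_secretion": cl_sec,
        "CL_hepatic": cl_hep,
        "CL_biliary": cl_bile,
        "CL_renal": cl_fil + cl_sec,
        "CL_total": cl_fil + cl_sec + cl_hep + cl_bile,
        "Vc": params.Vc * size_ratio,
        "Vp": params.Vp * size_ratio,
        "Q": params.Q * bsa_ratio,
        "transporter_ratio": individual.transporter_ratio,
    }


def _system_matrix(params: PBPKParameters, eff: dict[str, float]) -> np.ndarray:
    """5-state rate matrix: gut, central, peripheral, eliminated, unabsorbed."""
    ka, F = params.ka, params.F
    Vc, Vp, Q = eff["Vc"], eff["Vp"], eff["Q"]
    cl = eff["CL_total"]
    M = np.zeros((5, 5))
    M[0, 0] = -ka
    M[1, 0] = ka * F
    M[1, 1] = -(cl + Q) / Vc
    M[1, 2] = Q / Vp
    M[2, 1] = Q / Vc
    M[2, 2] = -Q / Vp
    M[3, 1] = cl / Vc
    M[4, 0] = ka * (1.0 - F)
    return M


def dose_mg_to_umol(dose_mg: float, molecular_weight: float = MTX_MOLECULAR_WEIGHT) -> float:
    return dose_mg / molecular_weight * 1000.0


def simulate_profile(params: PBPKParameters,
                     individual: Individual | None = None,
                     regimen: Regimen | None = None,
                     grid: np.ndarray | None = None,
                     dt: float = 0.05,
                     hepatic_multiplier: float = 1.0) -> ConcentrationProfile:
    """Simulate the plasma concentration-time profile for one individual.

    The default grid spans all dosing intervals at ``dt`` resolution.  A
    custom strictly increasing ``grid`` starting at 0 may be supplied; dose
    times must then coincide with grid points.
    """
    params.validate()
    if individual is None:
        individual = reference_individual()
    if regimen is None:
        raise ValueError("a Regimen is required")
    eff = scale_to_ckd(params, individual, hepatic_multiplier)
    M = _system_matrix(params, eff)

    if grid is None:
        t_end = regimen.interval_h * regimen.n_doses
        n_steps = int(round(t_end / dt))
        grid = np.linspace(0.0, t_end, n_steps + 1)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must start at 0 and be strictly increasing")

    dose_umol = dose_mg_to_umol(regimen.dose_mg, params.molecular_weight)
    dose_times = np.array([k * regimen.interval_h for k in range(regimen.n_doses)])
    # every dose time must sit on the grid (within rounding)
    for t_d in dose_times:
        if t_d > grid[-1] + 1e-9:
            continue
        if np.min(np.abs(grid - t_d)) > 1e-9:
            raise ValueError(f"dose time {t_d} h is not on the simulation grid")

    steps = np.diff(grid)
    propagators: dict[float, np.ndarray] = {}
    for h in np.unique(np.round(steps, 12)):
        propagators[h] = expm(M * h)

    y = np.zeros(5)
    amounts = np.empty((grid.size, 5))
    administered = np.empty(grid.size)
    given = 0.0
    for i, t in enumerate(grid):
        hit = np.abs(dose_times - t) <= 1e-9
        if hit.any():
            y[0] += dose_umol * int(hit.sum())
            given += dose_umol * int(hit.sum())
        amounts[i] = y
        administered[i] = given
        if i < steps.size:
            y = propagators[round(steps[i], 12)] @ y

    conc = amounts[:, 1] / eff["Vc"]
    if np.min(conc) < -1e-9:
        raise RuntimeError("negative concentrations beyond tolerance")
    return ConcentrationProfile(times_h=grid, conc_umol_L=np.maximum(conc, 0.0),
                                amounts=amounts, administered_umol=administered)


# ---------------------------------------------------------------------------
# virtual populations


def generate_virtual_population(stage: str, n: int, seed: int,
                                weight_cv: float = 0.15,
                                height_cv: float = 0.05) -> list[Individual]:
    """Draw ``n`` virtual individuals for a CKD stage.

    eGFR is uniform over the stage bounds; weight and height are lognormal
    around the reference adult; age is uniform on 20-70 y (age does not enter
    the kinetics and is demographic metadata only).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if stage not in STAGE_EGFR_BOUNDS:
        raise ValueError(f"unknown stage {stage!r}")
    lo, hi = STAGE_EGFR_BOUNDS[stage]
    rng = np.random.default_rng(seed)
    egfr = rng.uniform(lo, hi, n) if hi > lo else np.full(n, lo)
    weight = REFERENCE_WEIGHT_KG * rng.lognormal(0.0, weight_cv, n)
    height = REFERENCE_HEIGHT_CM * rng.lognormal(0.0, height_cv, n)
    age = rng.uniform(20.0, 70.0, n)
    return [Individual(float(a), float(h), float(w), float(e), stage)
            for a, h, w, e in zip(age, height, weight, egfr)]


# ---------------------------------------------------------------------------
# calibration

_DEFAULT_FREE = ("ka", "Vc", "Vp", "Q", "CL_sec")


def _default_bounds(params0: PBPKParameters) -> dict[str, tuple[float, float]]:
    fil = params0.cl_filtration_ref
    return {
        "ka": (0.2, 5.0),
        "Vc": (3.0, 60.0),
        "Vp": (5.0, 100.0),
        "Q": (0.5, 40.0),
        # keeps the secretion share of renal clearance inside 60-80%
        "CL_sec": (1.5 * fil, 4.0 * fil),
        "CL_hep": (0.1, 5.0),
        "CL_bile": (0.05, 5.0),
        "F": (0.2, 1.0),
        "fu": (0.2, 1.0),
    }


def calibrate_healthy(params0: PBPKParameters,
                      observations: pd.DataFrame,
                      bounds: dict[str, tuple[float, float]] | None = None,
                      seed: int = 0,
                      free: tuple[str, ...] = _DEFAULT_FREE,
                      n_starts: int = 4,
                      sim_dt: float = 0.1) -> tuple[PBPKParameters, dict]:
    """Fit healthy-reference parameters to concentration observations.

    Minimizes the sum of squared log10 residuals between simulated and
    observed concentrations (pooled over doses) with multi-start local
    optimization: the first start is ``params0``, the rest are seeded uniform
    draws in log-parameter space.  Parameters are optimized in log space
    under box bounds that keep the physiological invariants satisfiable.

    Returns the fitted parameters and a fit report (objective per start,
    convergence flags, active bounds).
    """
    obs = observations.loc[observations["conc_umol_L"] > 0]
    if obs.empty:
        raise ValueError("no positive-concentration observations")
    doses = np.unique(obs["dose_mg"].to_numpy(dtype=float))
    if doses.size < 2:
        raise ValueError("observations must span at least two doses")
    all_bounds = _default_bounds(params0)
    if bounds:
        all_bounds.update(bounds)
    box = [all_bounds[name] for name in free]
    log_box = [(math.log(lo), math.log(hi)) for lo, hi in box]

    t_end = float(obs["time_h"].max()) * 1.1 + sim_dt
    n_steps = int(round(t_end / sim_dt))
    grid = np.linspace(0.0, n_steps * sim_dt, n_steps + 1)
    by_dose = {d: g for d, g in obs.groupby("dose_mg")}

    ref = reference_individual()

    def build(x: np.ndarray) -> PBPKParameters:
        return replace(params0, **{name: math.exp(v) for name, v in zip(free, x)})

    def objective(x: np.ndarray) -> float:
        p = build(x)
        total = 0.0
        for d in doses:
            g = by_dose[d]
            try:
                prof = simulate_profile(p, ref, Regimen(dose_mg=float(d)), grid=grid)
            except (ValueError, RuntimeError):
                return 1e6
            pred = np.interp(g["time_h"].to_numpy(float), grid, prof.conc_umol_L)
            pred = np.maximum(pred, 1e-12)
            resid = np.log10(pred) - np.log10(g["conc_umol_L"].to_numpy(float))
            total += float(np.sum(resid**2))
        return total

    rng = np.random.default_rng(seed)
    x0_list = [np.array([math.log(getattr(params0, name)) for name in free])]
    for _ in range(max(n_starts - 1, 0)):
        x0_list.append(np.array([rng.uniform(lo, hi) for lo, hi in log_box]))

    results = []
    for x0 in x0_list:
        x0 = np.clip(x0, [b[0] for b in log_box], [b[1] for b in log_box])
        res = minimize(objective, x0, method="L-BFGS-B", bounds=log_box,
                       options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
        results.append(res)
    objectives = [float(r.fun) for r in results]
    best = results[int(np.argmin(objectives))]
    fitted = build(best.x)
    fitted.validate()

    active = [name for name, v, (lo, hi) in zip(free, best.x, log_box)
              if v - lo < 1e-6 or hi - v < 1e-6]
    report = {
        "objective": float(best.fun),
        "start_objectives": objectives,
        "n_starts": len(results),
        "converged": bool(best.success),
        "bound_active": active,
        "free": list(free),
        "n_obs": int(len(obs)),
    }
    return fitted, report


# ---------------------------------------------------------------------------
# evaluation metrics


@dataclass
class EvaluationMetrics:
    """Accuracy/precision summary of predicted vs observed pharmacokinetics.

    ``mrd`` is the fold-error summary of matched concentrations (root mean
    squared log10 deviation, exponentiated); ``gmfe_abs`` the geometric mean
    absolute fold error of per-study PK parameters (Cmax, AUC_last), which is
    >= 1 by construction; ``gmfr_signed`` the signed variant (geometric mean
    fold ratio), which can fall below 1 when under- and over-prediction
    cancel.  GOF fractions count concentration pairs within 2-fold and
    1.25-fold.
    """

    mrd: float
    gmfe_abs: float
    gmfr_signed: float
    frac_within_2fold: float
    frac_within_1p25fold: float
    n_conc_pairs: int
    n_dropped: int
    n_studies: int


def evaluate_model(predicted: pd.DataFrame, observed: pd.DataFrame,
                   mrd_sqrt: bool = True) -> EvaluationMetrics:
    """Compare predicted with observed concentration tables.

    Both frames need ``time_h`` and ``conc_umol_L``; pairs are matched on
    ``time_h`` plus whichever of ``study``, ``subject``, ``dose_mg`` are
    present in both.  Non-positive concentrations are dropped and counted.
    Per-study Cmax and AUC_last (trapezoid on the observation times) feed the
    GMFE; the study key is ``study`` if present, else ``(subject, dose_mg)``,
    else ``dose_mg``, else the whole table.

    ``mrd_sqrt=False`` computes the printed-literal variant without the
    square root (not a fold error; kept for comparison).
    """
    keys = [c for c in ("study", "subject", "dose_mg") if
            c in predicted.columns and c in observed.columns]
    merged = predicted.merge(observed, on=keys + ["time_h"],
                             suffixes=("_pred", "_obs"))
    if merged.empty:
        raise ValueError("no matched (key, time) observation pairs")
    ok = (merged["conc_umol_L_pred"] > 0) & (merged["conc_umol_L_obs"] > 0)
    n_dropped = int((~ok).sum())
    merged = merged.loc[ok]
    if merged.empty:
        raise ValueError("all matched pairs had non-positive concentrations")

    dlog = (np.log10(merged["conc_umol_L_pred"].to_numpy(float))
            - np.log10(merged["conc_umol_L_obs"].to_numpy(float)))
    x = float(np.sum(dlog**2) / dlog.size)
    mrd = 10.0 ** (math.sqrt(x) if mrd_sqrt else x)
    within2 = float(np.mean(np.abs(dlog) <= math.log10(2.0)))
    within125 = float(np.mean(np.abs(dlog) <= math.log10(1.25)))

    study_keys = (["study"] if "study" in keys else
                  [c for c in ("subject", "dose_mg") if c in keys]) or None
    ratios = []
    groups = merged.groupby(study_keys) if study_keys else [(None, merged)]
    n_studies = 0
    for _, g in groups:
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(float)
        cp = g["conc_umol_L_pred"].to_numpy(float)
        co = g["conc_umol_L_obs"].to_numpy(float)
        n_studies += 1
        ratios.append(cp.max() / co.max())  # Cmax
        if t.size > 1:
            ratios.append(np.trapezoid(cp, t) / np.trapezoid(co, t))  # AUC_last
    logr = np.log10(np.asarray(ratios))
    gmfe_abs = float(10.0 ** np.mean(np.abs(logr)))
    gmfr_signed = float(10.0 ** np.mean(logr))
    return EvaluationMetrics(mrd=float(mrd), gmfe_abs=gmfe_abs,
                             gmfr_signed=gmfr_signed,
                             frac_within_2fold=within2,
                             frac_within_1p25fold=within125,
                             n_conc_pairs=int(dlog.size), n_dropped=n_dropped,
                             n_studies=n_studies)


# ---------------------------------------------------------------------------
# sensitivity

_SENS_PARAMS = ("ka", "F", "fu", "Vc", "Vp", "Q", "CL_sec", "CL_hep", "CL_bile")


def sensitivity_analysis(params: PBPKParameters,
                         individual: Individual | None = None,
                         regimen: Regimen | None = None,
                         rel_step: float = 0.05,
                         parameters: tuple[str, ...] = _SENS_PARAMS,
                         dt: float = 0.05) -> dict[str, dict[str, float]]:
    """Central-difference log-log elasticities of Cmax and AUC_last.

    Returns ``{parameter: {"cmax": dlnCmax/dlntheta, "auc_last": ...}}``.
    """
    if not 0.0 < rel_step <= 0.5:
        raise ValueError("rel_step must be in (0, 0.5]")
    if individual is None:
        individual = reference_individual()
    if regimen is None:
        regimen = Regimen(dose_mg=7.5)

    def outputs(p: PBPKParameters) -> tuple[float, float]:
        prof = simulate_profile(p, individual, regimen, dt=dt)
        return prof.cmax, prof.auc_last

    out: dict[str, dict[str, float]] = {}
    dln = math.log(1.0 + rel_step) - math.log(1.0 - rel_step)
    for name in parameters:
        base = getattr(params, name)
        up = replace(params, **{name: base * (1.0 + rel_step)})
        dn = replace(params, **{name: base * (1.0 - rel_step)})
        c_up, a_up = outputs(up)
        c_dn, a_dn = outputs(dn)
        out[name] = {
            "cmax": (math.log(c_up) - math.log(c_dn)) / dln,
            "auc_last": (math.log(a_up) - math.log(a_dn)) / dln,
        }
    return out


# ---------------------------------------------------------------------------
# flat key=value parameter files

_PARAM_FIELDS = ("molecular_weight", "fu", "ka", "F", "Vc", "Vp", "Q",
                 "CL_sec", "CL_hep", "CL_bile", "GFR_ref")


def write_parameters(params: PBPKParameters, path: str | Path) -> None:
    lines = [f"{name} = {getattr(params, name)!r}" for name in _PARAM_FIELDS]
    Path(path).write_text("\n".join(lines) + "\n")


def read_parameters(path: str | Path) -> PBPKParameters:
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line: {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _PARAM_FIELDS:
            raise ValueError(f"unknown parameter {key!r}")
        values[key] = float(val.strip())
    params = PBPKParameters(**values)
    params.validate()
    return params
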