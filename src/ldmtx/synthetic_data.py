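"""Synthetic inputs for every pipeline stage.

Everything downstream (signal detection, spline fitting, PBPK calibration)
is exercised on data generated here, so the whole pipeline runs with no
downloads:

* FAERS-dialect report tables (DEMO/DRUG/INDI/REAC, "$"-delimited) with
  planted disproportionality signals, versioned duplicate cases, drug-name
  variants from the synonym table, and a renal-impairment indication
  subcohort — a synthetic stand-in for a real spontaneous-report extract;
* noisy concentration-time observations from known PBPK parameters — a
  synthetic stand-in for digitized healthy-volunteer curves;
* dose-Cmax pair tables drawn around a reference spline;
* a demographic fixture whose column margins reproduce the published
  renal-impairment case characteristics exactly (2,663 cases).

All randomness flows through one ``numpy.random.default_rng(seed)`` per
call; identical plans produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pbpk
from .faers_signal import load_synonym_table
from .rcs_model import RCSModel, evaluate_rcs

__all__ = [
    "SignalPlan",
    "PKObservationPlan",
    "default_signal_plan",
    "generate_report_frames",
    "generate_faers_tables",
    "generate_pk_observations",
    "generate_dose_cmax_pairs",
    "generate_table1_fixture",
    "TABLE1_MARGINS",
    "TABLE1_N",
]

# ---------------------------------------------------------------------------
# FAERS-style corpus

# baseline per-case reporting probability of each reaction PT
_DEFAULT_PT_RATES = {
    "Nausea": 0.12, "Fatigue": 0.10, "Rash": 0.08, "Diarrhoea": 0.08,
    "Headache": 0.07, "Pyrexia": 0.06, "Vomiting": 0.05, "Arthralgia": 0.05,
    "Dizziness": 0.05, "Anaemia": 0.04, "Stomatitis": 0.03, "Pneumonia": 0.03,
    "Malaise": 0.03, "Fall": 0.03, "Thrombocytopenia": 0.01,
    "Neutropenia": 0.01, "Transaminases increased": 0.01,
    "Accidental overdose": 0.01, "Pancytopenia": 0.005,
    "Febrile neutropenia": 0.005, "Pneumonitis": 0.004,
    "Product quality issue": 0.005, "Toxic epidermal necrolysis": 0.002,
}

_RENAL_INDICATIONS = ("Renal failure", "Renal impairment",
                      "Chronic kidney disease", "Acute kidney injury",
                      "Uraemia")
_OTHER_INDICATIONS = ("Rheumatoid arthritis", "Psoriasis",
                      "Psoriatic arthropathy", "Crohn's disease")
_COMPARATOR_DRUGS = ("prednisone", "ibuprofen", "folic acid", "etanercept",
                     "adalimumab", "lisinopril", "furosemide",
                     "hydroxychloroquine")
_DOSE_CHOICES = (2.5, 7.5, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class SignalPlan:
    """Recipe for one synthetic spontaneous-report corpus."""

    background_pt_rates: dict = field(default_factory=lambda: dict(_DEFAULT_PT_RATES))
    planted_effects: dict = field(default_factory=dict)  # (drug, pt) -> rate ratio
    n_cases: int = 5000
    renal_fraction: float = 0.30
    seed: int = 0
    target_drug: str = "methotrexate"
    drug_prevalence: float = 0.30        # P(case reports the target drug)
    duplicate_fraction: float = 0.05     # share of cases with an extra version

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if not self.background_pt_rates:
            raise ValueError("empty PT vocabulary")
        for pt, p in self.background_pt_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate for {pt!r} outside [0, 1]")
        for key, ratio in self.planted_effects.items():
            if not (np.isfinite(ratio) and ratio >= 0):
                raise ValueError(f"rate ratio for {key} must be finite and >= 0")
        if not 0.0 <= self.renal_fraction <= 1.0:
            raise ValueError("renal_fraction outside [0, 1]")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction outside [0, 1]")
        if not 0.0 < self.drug_prevalence <= 1.0:
            raise ValueError("drug_prevalence outside (0, 1]")


def default_signal_plan(seed: int = 0, n_cases: int = 5000,
                        planted_ratio: float = 8.0) -> SignalPlan:
    """Corpus with one planted signal: target drug x Thrombocytopenia."""
    return SignalPlan(
        planted_effects={("methotrexate", "Thrombocytopenia"): planted_ratio},
        n_cases=n_cases, seed=seed)


def _variants_by_generic() -> dict[str, list[str]]:
    table = load_synonym_table()
    out: dict[str, list[str]] = {}
    for variant, generic in table.items():
        out.setdefault(generic, []).append(variant)
    for v in out.values():
        v.sort()
    return out


def generate_report_frames(plan: SignalPlan) -> dict[str, pd.DataFrame]:
    """Build the four report tables in memory (see module docstring).

    Duplicate cases share a CASE ID across two strictly increasing PRIMARY
    IDs; the higher PRIMARY ID is the current version, mirroring report
    versioning so deduplication is exercisable.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    n = plan.n_cases
    case_ids = 1_000_000 + np.arange(n)

    sex = rng.choice(["F", "M", ""], size=n, p=[0.55, 0.30, 0.15])
    age = np.round(rng.uniform(18, 90, size=n), 0)
    age_missing = rng.random(n) < 0.18
    country = rng.choice(["CA", "US", "ES", "GB", "FR", ""], size=n,
                         p=[0.37, 0.20, 0.11, 0.15, 0.15, 0.02])
    occp = rng.choice(["MD", "CN", "HP", "OT", ""], size=n,
                      p=[0.41, 0.24, 0.24, 0.08, 0.03])
    year = rng.choice(np.arange(2004, 2025), size=n,
                      p=_year_weights())
    event_dt = np.char.add(year.astype(str), "0601")

    has_target = rng.random(n) < plan.drug_prevalence
    renal = rng.random(n) < plan.renal_fraction
    indication = np.where(
        renal,
        rng.choice(_RENAL_INDICATIONS, size=n),
        rng.choice(_OTHER_INDICATIONS, size=n))
    comparator = rng.choice(_COMPARATOR_DRUGS, size=n)
    dose = rng.choice(len(_DOSE_CHOICES) + 1, size=n)  # last index = missing

    pts = list(plan.background_pt_rates)
    base = np.array([plan.background_pt_rates[pt] for pt in pts])
    probs = np.tile(base, (n, 1))
    for (drug_name, pt), ratio in plan.planted_effects.items():
        if pt not in pts:
            raise ValueError(f"planted PT {pt!r} not in background vocabulary")
        col = pts.index(pt)
        if drug_name == plan.target_drug:
            probs[has_target, col] = np.clip(base[col] * ratio, 0.0, 0.95)
    reactions = rng.random((n, len(pts))) < probs

    # report versions: every case has version 2 (current); a seeded subset
    # also has version 1 (an earlier duplicate with the same content)
    n_dup = int(round(plan.duplicate_fraction * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    is_dup = np.zeros(n, dtype=bool)
    is_dup[dup_idx] = True

    variants = _variants_by_generic()
    target_variants = variants.get(plan.target_drug, [plan.target_drug])
    target_names = rng.choice(target_variants, size=n)

    demo_rows, drug_rows, indi_rows, reac_rows = [], [], [], []

    def emit(i: int, version: int) -> None:
        pid = int(case_ids[i]) * 10 + version
        cid = int(case_ids[i])
        demo_rows.append((pid, cid, sex[i],
                          "" if age_missing[i] else f"{age[i]:.0f}",
                          "YR", occp[i], country[i], event_dt[i]))
        seq = 1
        if has_target[i]:
            amt = "" if dose[i] >= len(_DOSE_CHOICES) else f"{_DOSE_CHOICES[dose[i]]}"
            drug_rows.append((pid, cid, seq, "PS", target_names[i], amt, "MG"))
            seq += 1
        drug_rows.append((pid, cid, seq, "C", comparator[i], "", ""))
        indi_rows.append((pid, cid, 1, indication[i]))
        for j, pt in enumerate(pts):
            if reactions[i, j]:
                reac_rows.append((pid, cid, pt))

    for i in range(n):
        if is_dup[i]:
            emit(i, 1)
        emit(i, 2)

    demo = pd.DataFrame(demo_rows, columns=[
        "primaryid", "caseid", "sex", "age", "age_cod", "occp_cod",
        "reporter_country", "event_dt"])
    drug = pd.DataFrame(drug_rows, columns=[
        "primaryid", "caseid", "drug_seq", "role_cod", "drugname",
        "dose_amt", "dose_unit"])
    indi = pd.DataFrame(indi_rows, columns=[
        "primaryid", "caseid", "indi_drug_seq", "indi_pt"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "caseid", "pt"])
    return {"DEMO": demo, "DRUG": drug, "INDI": indi, "REAC": reac}


def _year_weights() -> np.ndarray:
    # sparse early years, two thirds of reports in the recent period
    years = np.arange(2004, 2025)
    w = np.where(years <= 2012, 0.2, np.where(years <= 2018, 2.0, 4.0))
    return w / w.sum()


def generate_faers_tables(plan: SignalPlan, out_dir: str | Path) -> dict[str, Path]:
    """Write the four "$"-delimited ASCII tables to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = generate_report_frames(plan)
    paths = {}
    for name, df in frames.items():
        path = out_dir / f"{name}.txt"
        df.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# PK observations


@dataclass(frozen=True)
class PKObservationPlan:
    """Recipe for synthetic concentration-time observation tables."""

    true_parameters: pbpk.PBPKParameters
    doses_mg: tuple = (7.5, 15.0)
    sampling_times_h: tuple = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0,
                               12.0, 24.0, 36.0, 48.0)
    noise_cv: float = 0.15
    n_subjects_per_dose: int = 6
    seed: int = 0

    def validate(self) -> None:
        self.true_parameters.validate()
        if any(d <= 0 for d in self.doses_mg):
            raise ValueError("doses must be > 0")
        t = np.asarray(self.sampling_times_h)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be nonnegative and strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_subjects_per_dose < 1:
            raise ValueError("n_subjects_per_dose must be >= 1")


def generate_pk_observations(plan: PKObservationPlan) -> pd.DataFrame:
    """Simulate reference-adult profiles and add multiplicative noise.

    The noise factor is lognormal with unit mean and coefficient of
    variation ``noise_cv``; a zero-noise plan returns the model output
    exactly.  Columns: subject, dose_mg, time_h, conc_umol_L.
    """
    plan.validate()
    rng = np.random.default_rng(plan.seed)
    times = np.asarray(plan.sampling_times_h, dtype=float)
    t_end = float(times.max())
    grid = np.linspace(0.0, t_end, int(round(t_end / 0.05)) + 1)
    ref = pbpk.reference_individual()
    sigma = float(np.sqrt(np.log1p(plan.noise_cv**2)))
    rows = []
    subject = 0
    for dose in plan.doses_mg:
        prof = pbpk.simulate_profile(plan.true_parameters, ref,
                                     pbpk.Regimen(dose_mg=float(dose)), grid=grid)
        clean = np.interp(times, grid, prof.conc_umol_L)
        for _ in range(plan.n_subjects_per_dose):
            subject += 1
            if plan.noise_cv > 0:
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=times.size)
            else:
                noise = np.ones_like(times)
            for t, c in zip(times, clean * noise):
                rows.append((subject, float(dose), float(t), float(c)))
    return pd.DataFrame(rows, columns=["subject", "dose_mg", "time_h",
                                       "conc_umol_L"])


# ---------------------------------------------------------------------------
# dose-Cmax pairs


def generate_dose_cmax_pairs(model: RCSModel, dose_grid, noise_sd: float,
                             n_per_dose: int, seed: int) -> pd.DataFrame:
    """Draw Cmax ~ Normal(spline(dose), noise_sd), truncated at zero."""
    doses = np.asarray(list(dose_grid), dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be >= 1")
    rng = np.random.default_rng(seed)
    dose_col = np.repeat(doses, n_per_dose)
    mean = evaluate_rcs(model, dose_col)
    cmax = np.maximum(mean + rng.normal(0.0, noise_sd, size=dose_col.size)
                      if noise_sd > 0 else mean, 0.0)
    return pd.DataFrame({"dose_mg": dose_col, "cmax_umol_L": cmax})


# ---------------------------------------------------------------------------
# demographic fixture with exact published margins

TABLE1_N = 2663

# column -> ordered (label, count); every column sums to 2,663
TABLE1_MARGINS: dict[str, tuple[tuple[str, int], ...]] = {
    "sex": (("Female", 1427), ("Male", 780), ("Missing or unknown", 456)),
    "age_group": (("0-18", 198), ("19-45", 130), ("45-65", 641),
                  ("65-100", 1214), ("Missing or unknown", 480)),
    "dose_group": (("2.5 mg", 316), ("10 mg", 201), ("15 mg", 132),
                   ("20 mg", 142), ("Other doses", 284),
                   ("Missing or unknown", 1588)),
    "reporter": (("Physician", 1091), ("Consumer", 648),
                 ("Health professional", 636), ("Other reporter", 208),
                 ("Missing or unknown", 80)),
    "country": (("CA", 995), ("US", 527), ("ES", 302), ("Other country", 796),
                ("Missing or unknown", 43)),
    "year_group": (("2019-2024", 1732), ("2013-2018", 923), ("2004-2012", 8)),
}

# age values are drawn inside half-open bins so the overlapping printed bin
# edges (45, 65) resolve to the upper bin
_AGE_BIN_RANGES = {"0-18": (0, 18), "19-45": (19, 44), "45-65": (45, 64),
                   "65-100": (65, 100)}
_YEAR_BIN_RANGES = {"2019-2024": (2019, 2024), "2013-2018": (2013, 2018),
                    "2004-2012": (2004, 2012)}
_DOSE_VALUES = {"2.5 mg": 2.5, "10 mg": 10.0, "15 mg": 15.0, "20 mg": 20.0}


def generate_table1_fixture(seed: int = 0) -> pd.DataFrame:
    """2,663 demographic case rows whose column margins match the published
    renal-impairment case characteristics exactly.

    Columns are shuffled independently (the published table reports margins
    only, not joint distributions), so any single-column tabulation
    reproduces the printed counts while joints are synthetic.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for col, margins in TABLE1_MARGINS.items():
        labels = np.concatenate([np.repeat(lbl, cnt) for lbl, cnt in margins])
        assert labels.size == TABLE1_N
        data[col] = rng.permutation(labels)
    df = pd.DataFrame(data)
    df.insert(0, "case_id", 2_000_000 + np.arange(TABLE1_N))

    age = np.full(TABLE1_N, np.nan)
    for lbl, (lo, hi) in _AGE_BIN_RANGES.items():
        mask = df["age_group"] == lbl
        age[mask.to_numpy()] = rng.integers(lo, hi + 1, int(mask.sum()))
    df["age_years"] = age
    year = np.full(TABLE1_N, np.nan)
    for lbl, (lo, hi) in _YEAR_BIN_RANGES.items():
        mask = df["year_group"] == lbl
        year[mask.to_numpy()] = rng.integers(lo, hi + 1, int(mask.sum()))
    df["report_year"] = year
    df["mtx_dose_mg"] = df["dose_group"].map(_DOSE_VALUES).astype(float)
    other = df["dose_group"] == "Other doses"
    df.loc[other, "mtx_dose_mg"] = rng.choice([5.0, 12.5, 17.5, 25.0],
                                              int(other.sum()))
    return df
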