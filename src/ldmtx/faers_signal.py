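"""ETL and disproportionality analysis for FAERS-dialect report tables.

The spontaneous-report extract arrives as four "$"-delimited ASCII tables
(DEMO, DRUG, INDI, REAC) keyed by PRIMARY ID / CASE ID.  The pipeline merges
them into per-case records, normalizes drug names through a synonym table,
restricts to the renal-impairment indication cohort, deduplicates on CASE ID
(keeping the highest PRIMARY ID, i.e. the current version of the report),
and purges reaction preferred terms (PTs) from non-adverse-reaction classes.

Signal detection runs three disproportionality statistics on the drug x PT
2x2 table (a = target drug & target PT, b = target drug & other PTs,
c = other drugs & target PT, d = neither):

* PRR  = (a/(a+b)) / (c/(c+d)) with the Pearson chi-square,
  flagged when a >= 3, PRR >= 2 and chi2 >= 4;
* ROR  = ad/bc with a Wald 95% CI on the log scale,
  flagged when a >= 3 and the CI lower bound exceeds 1
  (Haldane-Anscombe +0.5 applied to every cell when any cell is zero);
* IC   = log2((a + 0.5) / (E + 0.5)) with E = (a+b)(a+c)/N — the shrinkage
  information component — and its lower credibility bound
  IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2.0 (a+0.5)^(-3/2),
  flagged when a >= 3 and IC025 > 0.

A PT is a signal only when all three flags hold (the three-way rule).  The
default counting unit is the case-PT pair: each deduplicated case contributes
each of its reaction PTs once; case-level counting is available via
``unit="case"``.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm  # noqa: F401  (documented z-quantile source)

from .config import CHI2_MIN, IC025_MIN, MIN_REPORTS, PRR_MIN, ROR_CI_LOW_MIN

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "load_tables",
    "load_synonym_table",
    "load_pt_soc",
    "load_renal_pts",
    "load_exclusions",
    "normalize_drug_names",
    "build_cases",
    "filter_renal_cohort",
    "deduplicate",
    "exclude_non_adr_pts",
    "build_contingency",
    "compute_prr",
    "compute_ror",
    "compute_ic",
    "detect_signals",
    "aggregate_by_soc",
    "run_signal_pipeline",
]

TABLE_NAMES = ("DEMO", "DRUG", "INDI", "REAC")
_Z95 = 1.959963984540054  # norm.ppf(0.975)

_REPORTER_CODES = {"MD": "physician", "CN": "consumer",
                   "HP": "health professional", "OT": "other"}


# ---------------------------------------------------------------------------
# bundled lookup fixtures (synthetic MedDRA-like vocabulary, synonym table)


def _data_path(name: str):
    return resources.files("ldmtx.data").joinpath(name)


def load_synonym_table() -> dict[str, str]:
    """Variant -> generic drug-name mapping (case-insensitive keys)."""
    with _data_path("drug_synonyms.csv").open() as fh:
        df = pd.read_csv(fh)
    return {v.strip().lower(): g for v, g in zip(df["variant"], df["generic"])}


def load_pt_soc() -> dict[str, str]:
    """PT -> System Organ Class lookup (synthetic stand-in dictionary)."""
    with _data_path("pt_soc.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["pt"], df["soc"]))


def load_renal_pts() -> frozenset[str]:
    """Indication PTs under the two renal-impairment high-level terms."""
    with _data_path("renal_indication_pts.csv").open() as fh:
        df = pd.read_csv(fh)
    return frozenset(df["pt"])


def load_exclusions() -> dict[str, str]:
    """Reaction PTs excluded as non-adverse-reaction classes."""
    with _data_path("pt_exclusions.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["pt"], df["excluded_class"]))


# ---------------------------------------------------------------------------
# loading


def _read_dollar_table(path: Path) -> tuple[pd.DataFrame, int]:
    """Read one "$"-delimited ASCII table; malformed rows are skipped."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path.name}: file is empty") from None
        n_fields = len(header)
        rows, skipped = [], 0
        for lineno, row in enumerate(reader, start=2):
            if len(row) != n_fields:
                skipped += 1
                logger.warning("%s: line %d has %d fields (expected %d); skipped",
                               path.name, lineno, len(row), n_fields)
                continue
            rows.append(row)
    if not rows:
        raise ValueError(f"{path.name}: no data rows")
    return pd.DataFrame(rows, columns=header), skipped


def load_tables(data_dir: str | Path) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Load DEMO/DRUG/INDI/REAC; returns tables and skipped-row counts."""
    data_dir = Path(data_dir)
    tables, report = {}, {}
    for name in TABLE_NAMES:
        path = data_dir / f"{name}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing table file {path}")
        df, skipped = _read_dollar_table(path)
        for key in ("primaryid", "caseid"):
            if key not in df.columns:
                raise ValueError(f"{name}.txt: missing key column {key!r}")
            df[key] = pd.to_numeric(df[key], errors="raise").astype("int64")
        tables[name] = df
        report[name] = skipped
    return tables, report


# ---------------------------------------------------------------------------
# cleaning


def normalize_drug_names(raw_names, synonym_table: dict[str, str]
                         ) -> tuple[list[str], Counter]:
    """Map raw drug-name strings to generic names.

    Lookup is case-insensitive and whitespace-trimmed; unmatched names pass
    through unchanged and are tallied in the returned counter.
    """
    unmatched: Counter = Counter()
    out = []
    for raw in raw_names:
        key = str(raw).strip().lower()
        if key in synonym_table:
            out.append(synonym_table[key])
        else:
            name = str(raw).strip()
            unmatched[name] += 1
            out.append(name)
    return out, unmatched


def build_cases(tables: dict[str, pd.DataFrame],
                synonym_table: dict[str, str] | None = None,
                target_drug: str = "methotrexate"
                ) -> tuple[pd.DataFrame, dict]:
    """Merge the four tables into one row per report version.

    Returns a frame with columns primary_id, case_id, sex, age_years,
    country, reporter, report_year, mtx_dose_mg, drugs / indication_pts /
    reaction_pts (frozensets), plus a report dict (unmatched drug names).
    """
    if synonym_table is None:
        synonym_table = load_synonym_table()
    demo = tables["DEMO"].copy()
    drug = tables["DRUG"].copy()
    indi = tables["INDI"]
    reac = tables["REAC"]

    normalized, unmatched = normalize_drug_names(drug["drugname"], synonym_table)
    drug["generic"] = normalized

    drug_sets = drug.groupby("primaryid")["generic"].agg(frozenset)
    dose = drug.loc[drug["generic"] == target_drug].copy()
    dose["dose_amt"] = pd.to_numeric(dose.get("dose_amt"), errors="coerce")
    dose_map = dose.groupby("primaryid")["dose_amt"].first()
    indi_sets = indi.groupby("primaryid")["indi_pt"].agg(frozenset)
    reac_sets = reac.groupby("primaryid")["pt"].agg(frozenset)

    sex = demo["sex"].where(demo["sex"].isin(["F", "M"]), "unknown")
    age = pd.to_numeric(demo["age"], errors="coerce")
    age = age.where(demo.get("age_cod", "YR").fillna("YR").isin(["YR", ""]), np.nan)
    year = pd.to_numeric(demo["event_dt"].str.slice(0, 4), errors="coerce")

    cases = pd.DataFrame({
        "primary_id": demo["primaryid"],
        "case_id": demo["caseid"],
        "sex": sex,
        "age_years": age,
        "country": demo.get("reporter_country", pd.Series(dtype=str)),
        "reporter": demo.get("occp_cod", pd.Series(dtype=str)).map(
            _REPORTER_CODES).fillna("unknown"),
        "report_year": year,
        "mtx_dose_mg": demo["primaryid"].map(dose_map),
        "drugs": demo["primaryid"].map(drug_sets),
        "indication_pts": demo["primaryid"].map(indi_sets),
        "reaction_pts": demo["primaryid"].map(reac_sets),
    })
    empty = frozenset()
    for col in ("drugs", "indication_pts", "reaction_pts"):
        cases[col] = cases[col].apply(lambda s: s if isinstance(s, frozenset) else empty)
    report = {"unmatched_drug_names": dict(unmatched),
              "n_unmatched": int(sum(unmatched.values()))}
    return cases, report


def filter_renal_cohort(cases: pd.DataFrame,
                        renal_pt_set: frozenset[str] | set[str]) -> pd.DataFrame:
    """Keep cases whose indication PTs intersect the renal-impairment set."""
    if not renal_pt_set:
        raise ValueError("renal PT set must be nonempty")
    renal = frozenset(renal_pt_set)
    mask = cases["indication_pts"].apply(lambda s: bool(s & renal))
    return cases.loc[mask].reset_index(drop=True)


def deduplicate(cases: pd.DataFrame) -> pd.DataFrame:
    """One record per CASE ID: the version with the highest PRIMARY ID wins."""
    if cases.empty:
        return cases.reset_index(drop=True)
    idx = cases.groupby("case_id")["primary_id"].idxmax()
    out = cases.loc[idx].sort_values("primary_id", kind="mergesort")
    return out.reset_index(drop=True)


def exclude_non_adr_pts(cases: pd.DataFrame,
                        exclusion_classes: dict[str, str]
                        ) -> tuple[pd.DataFrame, dict]:
    """Purge excluded reaction PTs; drop (and count) cases left with none."""
    excluded = frozenset(exclusion_classes)
    out = cases.copy()
    purged = Counter()

    def purge(s: frozenset) -> frozenset:
        hit = s & excluded
        for pt in hit:
            purged[pt] += 1
        return s - hit

    out["reaction_pts"] = out["reaction_pts"].apply(purge)
    keep = out["reaction_pts"].apply(bool)
    n_dropped = int((~keep).sum())
    report = {"pts_purged": dict(purged), "cases_dropped_no_reactions": n_dropped}
    return out.loc[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# disproportionality statistics


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug x event report counts."""

    a: int  # target drug & target PT
    b: int  # target drug & other PTs
    c: int  # other drugs & target PT
    d: int  # other drugs & other PTs

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be nonnegative")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PRRResult:
    prr: float
    chi2: float
    flag: bool
    valid: bool = True


@dataclass(frozen=True)
class RORResult:
    ror: float
    ci95: tuple[float, float]
    flag: bool
    corrected: bool = False


@dataclass(frozen=True)
class ICResult:
    ic: float
    ic025: float
    flag: bool


def compute_prr(t: ContingencyTable, yates: bool = False,
                min_reports: int = MIN_REPORTS, prr_min: float = PRR_MIN,
                chi2_min: float = CHI2_MIN) -> PRRResult:
    """Proportional reporting ratio with its Pearson chi-square.

    ``yates=True`` applies the continuity correction to the chi-square
    (off by default; the classic rule uses the uncorrected statistic).
    Zero margins yield a flagged-invalid result.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return PRRResult(prr=math.nan, chi2=math.nan, flag=False, valid=False)
    num = a / (a + b)
    den = c / (c + d)
    if den == 0.0:
        if num == 0.0:
            return PRRResult(prr=math.nan, chi2=math.nan, flag=False, valid=False)
        prr = math.inf  # PT reported for the drug only
    else:
        prr = num / den
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - t.N / 2.0, 0.0)
    chi2 = t.N * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    flag = (a >= min_reports) and (prr >= prr_min) and (chi2 >= chi2_min)
    return PRRResult(prr=prr, chi2=chi2, flag=bool(flag))


def compute_ror(t: ContingencyTable, min_reports: int = MIN_REPORTS,
                ci_low_min: float = ROR_CI_LOW_MIN) -> RORResult:
    """Reporting odds ratio with a Wald 95% CI on the log scale.

    Any zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell) and the result is marked corrected; the report-count condition of
    the flag still uses the uncorrected ``a``.
    """
    corrected = min(t.a, t.b, t.c, t.d) == 0
    shift = 0.5 if corrected else 0.0
    a, b, c, d = (t.a + shift, t.b + shift, t.c + shift, t.d + shift)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(ror) - _Z95 * se)
    hi = math.exp(math.log(ror) + _Z95 * se)
    flag = (t.a >= min_reports) and (lo > ci_low_min)
    return RORResult(ror=ror, ci95=(lo, hi), flag=bool(flag), corrected=corrected)


def compute_ic(t: ContingencyTable, min_reports: int = MIN_REPORTS,
               ic025_min: float = IC025_MIN) -> ICResult:
    """Shrinkage information component and its lower credibility bound.

    The +0.5 shrinkage keeps the statistic finite for zero cells; the IC025
    closed form approximates the 2.5th percentile of the gamma posterior of
    the observed-to-expected ratio.
    """
    a = t.a
    E = (t.a + t.b) * (t.a + t.c) / t.N
    ic = math.log2((a + 0.5) / (E + 0.5))
    ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    flag = (a >= min_reports) and (ic025 > ic025_min)
    return ICResult(ic=ic, ic025=ic025, flag=bool(flag))


# ---------------------------------------------------------------------------
# cohort-level detection


def _pair_counts(cases: pd.DataFrame, drug: str) -> tuple[pd.Series, pd.Series, int, int]:
    """Per-PT report counts for drug and non-drug cases (case-PT pairs)."""
    has_drug = cases["drugs"].apply(lambda s: drug in s)
    long = cases[["reaction_pts"]].copy()
    long["has_drug"] = has_drug
    long = long.explode("reaction_pts").dropna(subset=["reaction_pts"])
    by_pt = long.groupby(["reaction_pts", "has_drug"]).size().unstack(fill_value=0)
    a_by_pt = by_pt[True] if True in by_pt.columns else pd.Series(0, index=by_pt.index)
    c_by_pt = by_pt[False] if False in by_pt.columns else pd.Series(0, index=by_pt.index)
    n_drug_pairs = int(long["has_drug"].sum())
    n_pairs = int(len(long))
    return a_by_pt, c_by_pt, n_drug_pairs, n_pairs


def build_contingency(cases: pd.DataFrame, drug: str, pt: str,
                      unit: str = "case_pt_pair") -> ContingencyTable:
    """2x2 table for one (drug, PT) pair over a deduplicated cohort.

    ``unit="case_pt_pair"`` counts each case once per reaction PT
    (N = number of case-PT pairs); ``unit="case"`` counts whole cases.
    A drug absent from the corpus yields a = b = 0 (logged).
    """
    has_drug = cases["drugs"].apply(lambda s: drug in s)
    has_pt = cases["reaction_pts"].apply(lambda s: pt in s)
    if unit == "case":
        a = int((has_drug & has_pt).sum())
        b = int((has_drug & ~has_pt).sum())
        c = int((~has_drug & has_pt).sum())
        d = int((~has_drug & ~has_pt).sum())
    elif unit == "case_pt_pair":
        n_pts = cases["reaction_pts"].apply(len)
        a = int((has_drug & has_pt).sum())
        c = int((~has_drug & has_pt).sum())
        b = int(n_pts[has_drug].sum()) - a
        d = int(n_pts[~has_drug].sum()) - c
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    if a + b == 0:
        logger.warning("drug %r absent from corpus (a=b=0)", drug)
    return ContingencyTable(a, b, c, d)


def detect_signals(cases: pd.DataFrame, drug: str,
                   pt_soc: dict[str, str] | None = None,
                   unit: str = "case_pt_pair",
                   min_reports: int = MIN_REPORTS) -> pd.DataFrame:
    """Run the three disproportionality methods for every PT with a >= 1.

    Expects a cleaned, deduplicated cohort.  Returns one row per PT sorted
    by report count (descending, ties by PT name) with the statistics, the
    per-method flags, and the three-way ``flag_signal``.
    """
    if pt_soc is None:
        pt_soc = load_pt_soc()
    if unit not in ("case_pt_pair", "case"):
        raise ValueError(f"unknown counting unit {unit!r}")

    has_drug = cases["drugs"].apply(lambda s: drug in s)
    if unit == "case_pt_pair":
        a_by_pt, c_by_pt, n_drug, n_total = _pair_counts(cases, drug)
    else:
        long = cases[["reaction_pts"]].copy()
        long["has_drug"] = has_drug
        long = long.explode("reaction_pts").dropna(subset=["reaction_pts"])
        grp = long.groupby(["reaction_pts", "has_drug"]).size().unstack(fill_value=0)
        a_by_pt = grp.get(True, pd.Series(0, index=grp.index))
        c_by_pt = grp.get(False, pd.Series(0, index=grp.index))
        n_drug = int(has_drug.sum())
        n_total = int(len(cases))

    rows = []
    for pt in a_by_pt.index:
        a = int(a_by_pt.get(pt, 0))
        if a < 1:
            continue
        c = int(c_by_pt.get(pt, 0))
        b = n_drug - a
        d = (n_total - n_drug) - c
        table = ContingencyTable(a, b, c, d)
        prr = compute_prr(table, min_reports=min_reports)
        ror = compute_ror(table, min_reports=min_reports)
        ic = compute_ic(table, min_reports=min_reports)
        rows.append({
            "pt": pt,
            "soc": pt_soc.get(pt, "Unmapped"),
            "a": a, "b": b, "c": c, "d": d,
            "prr": prr.prr, "chi2": prr.chi2,
            "ror": ror.ror, "ror_low": ror.ci95[0], "ror_high": ror.ci95[1],
            "ic": ic.ic, "ic025": ic.ic025,
            "flag_prr": prr.flag, "flag_ror": ror.flag, "flag_bcpnn": ic.flag,
            "flag_signal": prr.flag and ror.flag and ic.flag,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    return out.sort_values(["a", "pt"], ascending=[False, True]).reset_index(drop=True)


def aggregate_by_soc(signals: pd.DataFrame) -> pd.DataFrame:
    """Signal counts and shares per System Organ Class (flagged PTs only)."""
    if signals.empty or "flag_signal" not in signals.columns:
        return pd.DataFrame(columns=["soc", "n_signals", "share"])
    flagged = signals.loc[signals["flag_signal"]]
    if flagged.empty:
        return pd.DataFrame(columns=["soc", "n_signals", "share"])
    counts = flagged.groupby("soc").size().sort_values(ascending=False)
    out = counts.reset_index()
    out.columns = ["soc", "n_signals"]
    out["share"] = out["n_signals"] / out["n_signals"].sum()
    return out


# ---------------------------------------------------------------------------
# convenience pipeline


def run_signal_pipeline(data_dir: str | Path, drug: str = "methotrexate",
                        renal_only: bool = True, unit: str = "case_pt_pair",
                        min_reports: int = MIN_REPORTS) -> dict:
    """Load -> merge -> cohort-filter -> dedup -> exclude -> detect.

    Returns a dict with the signal table, the SOC summary and a per-stage
    attrition log (record counts after every cleaning step).
    """
    tables, load_report = load_tables(data_dir)
    cases, merge_report = build_cases(tables, target_drug=drug)
    attrition = {"loaded_demo_rows": int(len(cases)),
                 "skipped_rows": load_report,
                 **merge_report}
    if renal_only:
        cases = filter_renal_cohort(cases, load_renal_pts())
        attrition["after_renal_filter"] = int(len(cases))
    cases = deduplicate(cases)
    attrition["after_dedup"] = int(len(cases))
    cases, excl_report = exclude_non_adr_pts(cases, load_exclusions())
    attrition["after_pt_exclusion"] = int(len(cases))
    attrition.update(excl_report)
    signals = detect_signals(cases, drug, unit=unit, min_reports=min_reports)
    soc_summary = aggregate_by_soc(signals)
    return {"cases": cases, "signals": signals, "soc_summary": soc_summary,
            "attrition": attrition}
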