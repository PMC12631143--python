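"""Restricted cubic spline (RCS) dose->Cmax model.

A 4-knot restricted cubic spline regresses the weekly-dose maximum plasma
concentration (Cmax, µmol/L) on dose M (mg):

    Cmax = beta0 + beta1*M + beta2*f1(M) + beta3*f2(M)

where f1, f2 are truncated-power basis terms built on knots k1<k2<k3<k4 with
weights chosen so the fitted curve is exactly linear below k1 and above k4
(the "restricted" property).  Each cubic term ``(M - k)^3`` contributes only
where ``M > k``; without the truncation the cubic terms cancel identically
and the basis degenerates, so the truncated form is the only meaningful
reading.  Under the conventional scaling the basis is divided by
``(k4 - k1)^2`` so the nonlinear coefficients share the scale of the linear
term; the unscaled variant is kept for sensitivity.

``REFERENCE_MODEL`` carries the published healthy-adult coefficients and
knots used to anchor the 0.16 µmol/L baseline dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RCS_BETAS, RCS_KNOTS, RCS_KNOT_QUANTILES

__all__ = [
    "RCSModel",
    "REFERENCE_MODEL",
    "rcs_basis",
    "evaluate_rcs",
    "fit_rcs",
    "invert_for_dose",
    "read_model",
    "write_model",
]

_SCALINGS = ("harrell_scaled", "unscaled")


@dataclass(frozen=True)
class RCSModel:
    """Coefficients and knots of a 4-knot dose->Cmax spline."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    knots: tuple[float, float, float, float]
    basis_scaling: str = "harrell_scaled"

    def __post_init__(self):
        if len(self.knots) != 4:
            raise ValueError("exactly four knots are required")
        if not all(a < b for a, b in zip(self.knots, self.knots[1:])):
            raise ValueError("knots must be strictly increasing")
        if self.basis_scaling not in _SCALINGS:
            raise ValueError(f"basis_scaling must be one of {_SCALINGS}")

    @property
    def betas(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)


REFERENCE_MODEL = RCSModel(*RCS_BETAS, knots=RCS_KNOTS)


def _trunc_cubed(x: np.ndarray, k: float) -> np.ndarray:
    d = x - k
    return np.where(d > 0.0, d**3, 0.0)


def rcs_basis(dose, knots, scaling: str = "harrell_scaled"):
    """Nonlinear basis terms (f1, f2) of the 4-knot restricted cubic spline.

    ``fj`` uses interior knot ``kj`` with boundary-knot weights that cancel
    the quadratic and cubic trends beyond ``k4``:

        fj(M) = (M-kj)+^3 - (k4-kj)/(k4-k3)*(M-k3)+^3
                           + (k3-kj)/(k4-k3)*(M-k4)+^3

    divided by ``(k4-k1)^2`` under ``harrell_scaled``.
    """
    if scaling not in _SCALINGS:
        raise ValueError(f"scaling must be one of {_SCALINGS}")
    k1, k2, k3, k4 = knots
    if not (k1 < k2 < k3 < k4):
        raise ValueError("knots must be strictly increasing")
    x = np.asarray(dose, dtype=float)
    denom = (k4 - k1) ** 2 if scaling == "harrell_scaled" else 1.0

    def f(kj: float) -> np.ndarray:
        return (_trunc_cubed(x, kj)
                - (k4 - kj) / (k4 - k3) * _trunc_cubed(x, k3)
                + (k3 - kj) / (k4 - k3) * _trunc_cubed(x, k4)) / denom

    return f(k1), f(k2)


def evaluate_rcs(model: RCSModel, dose):
    """Predicted Cmax (µmol/L) at the given dose(s) (mg)."""
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    f1, f2 = rcs_basis(x, model.knots, model.basis_scaling)
    out = model.beta0 + model.beta1 * x + model.beta2 * f1 + model.beta3 * f2
    return float(out) if np.isscalar(dose) else out


def _validate_dataset(data: pd.DataFrame) -> pd.DataFrame:
    for col in ("dose_mg", "cmax_umol_L"):
        if col not in data.columns:
            raise ValueError(f"dataset must have a {col!r} column")
    if len(data) < 8:
        raise ValueError("at least 8 rows are required for fitting")
    if data["dose_mg"].nunique() < 4:
        raise ValueError("at least 4 distinct doses are required for fitting")
    if (data["dose_mg"] <= 0).any():
        raise ValueError("doses must be > 0")
    if (data["cmax_umol_L"] < 0).any():
        raise ValueError("cmax must be >= 0")
    return data


def fit_rcs(data: pd.DataFrame,
            knots: tuple[float, float, float, float] | None = None,
            scaling: str = "harrell_scaled") -> tuple[RCSModel, float]:
    """Ordinary-least-squares fit of the 4-knot spline.

    Knots default to the 0.05/0.275/0.725/0.95 empirical dose quantiles.
    Returns the fitted model together with its AIC,
    ``n*ln(RSS/n) + 2*4``.
    """
    data = _validate_dataset(data)
    dose = data["dose_mg"].to_numpy(dtype=float)
    y = data["cmax_umol_L"].to_numpy(dtype=float)
    if knots is None:
        knots = tuple(np.quantile(dose, RCS_KNOT_QUANTILES))
    if not all(a < b for a, b in zip(knots, knots[1:])):
        raise ValueError(f"degenerate knots {knots}: dose distribution too "
                         "concentrated for quantile placement")
    f1, f2 = rcs_basis(dose, knots, scaling)
    X = np.column_stack([np.ones_like(dose), dose, f1, f2])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        raise ValueError(
            "rank-deficient spline design (all doses in a linear region of "
            "the knot span); spread the doses across the knots")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = y.size
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * 4
    model = RCSModel(*map(float, beta), knots=tuple(map(float, knots)),
                     basis_scaling=scaling)
    return model, aic


def _turning_points(model: RCSModel, lo: float, hi: float,
                    n: int = 2001) -> list[float]:
    grid = np.linspace(lo, hi, n)
    vals = evaluate_rcs(model, grid)
    sign = np.sign(np.diff(vals))
    flips = np.nonzero(np.diff(sign) != 0)[0]
    return [float(grid[i + 1]) for i in flips]


def invert_for_dose(model: RCSModel, target_cmax: float,
                    dose_range: tuple[float, float],
                    tol: float = 1e-9) -> float:
    """Dose (mg) at which the spline attains ``target_cmax``.

    The model must be monotone increasing over ``dose_range`` (checked on a
    fine grid) and the target bracketed; the root is found by bisection to
    ``|f(d) - target| < tol``.
    """
    lo, hi = dose_range
    if not 0.0 <= lo < hi:
        raise ValueError("dose_range must satisfy 0 <= lo < hi")
    turns = _turning_points(model, lo, hi)
    if turns:
        raise ValueError(
            f"model is not monotone on [{lo}, {hi}]; turning points near "
            f"{[round(t, 3) for t in turns]}")
    f_lo = evaluate_rcs(model, lo)
    f_hi = evaluate_rcs(model, hi)
    if not (min(f_lo, f_hi) <= target_cmax <= max(f_lo, f_hi)):
        raise ValueError(
            f"target {target_cmax} not bracketed by model values "
            f"[{f_lo:.4g}, {f_hi:.4g}] on the dose range (no root)")
    increasing = f_hi >= f_lo
    a, b = lo, hi
    for _ in range(200):
        mid = 0.5 * (a + b)
        val = evaluate_rcs(model, mid)
        if abs(val - target_cmax) < tol:
            return mid
        if (val < target_cmax) == increasing:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# flat key=value model files


def write_model(model: RCSModel, path: str | Path) -> None:
    lines = [f"beta{i} = {b!r}" for i, b in enumerate(model.betas)]
    lines += [f"k{i + 1} = {k!r}" for i, k in enumerate(model.knots)]
    lines.append(f"scaling = {model.basis_scaling}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> RCSModel:
    values: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip()
    try:
        betas = [float(values[f"beta{i}"]) for i in range(4)]
        knots = tuple(float(values[f"k{i}"]) for i in range(1, 5))
    except KeyError as exc:
        raise ValueError(f"missing model key {exc}") from exc
    return RCSModel(*betas, knots=knots,
                    basis_scaling=values.get("scaling", "harrell_scaled"))
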