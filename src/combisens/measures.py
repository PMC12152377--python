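"""Dose-response curves, matrices and sensitivity measures.

Monotherapy responses are summarized by a three-parameter logistic (3PL)
viability curve

    f(x) = c + (1 - c) / (1 + exp(b * (ln x - ln e)))

with upper asymptote fixed at 1 (untreated viability), lower asymptote
``c`` (residual viability at saturating dose), slope ``b > 0`` and
inflection concentration ``e`` (µM).  From a fitted curve we derive
IC-levels (the concentration where the curve crosses a viability line) and
the CMax viability (the curve value at the drug's peak plasma
concentration).

Combination responses are summarized on a dose-response matrix — the grid
of viabilities over both drugs' screened concentrations, including the
zero-dose margins.  The combination CMax viability is the minimum
bilinearly interpolated viability over the concentration box
[0, CMax_A] x [0, CMax_B]; taking the minimum over the whole box (rather
than the corner value) captures synergy windows at sub-CMax doses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "CurveFit3PL",
    "RejectedFit",
    "DoseResponseMatrix",
    "inhibition_to_viability",
    "fit_3pl",
    "curve_eval",
    "ic_level",
    "cmax_viability",
    "assemble_matrix",
    "combination_cmax_viability",
    "curve_rmse_report",
]

#: curves with RMSE above this are considered unreliable and discarded
RMSE_MAX = 0.3
#: minimum number of dose-response points required to fit a curve
MIN_POINTS = 5


def inhibition_to_viability(inhibition):
    """Convert relative inhibition to relative viability in [0, 1].

    v = clamp((100 - inhibition) / 100, 0, 1).  Accepts scalars or arrays.
    """
    arr = np.asarray(inhibition, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("inhibition values must be finite")
    v = np.clip((100.0 - arr) / 100.0, 0.0, 1.0)
    return float(v) if np.isscalar(inhibition) or arr.ndim == 0 else v


@dataclass
class CurveFit3PL:
    """Fitted 3PL parameters plus goodness of fit."""

    b: float        # slope, > 0: curve decreases from 1 toward c
    c: float        # lower asymptote, viability in [0, 1]
    e: float        # inflection concentration, µM
    rmse: float
    n_points: int
    degenerate_flat: bool = False  # data carried (almost) no response range


@dataclass
class RejectedFit:
    """A curve fit that was refused, with the reason."""

    reason: str  # "min_points" | "rmse" | "optim_failure"
    n_points: int = 0
    rmse: float = float("nan")

    def __bool__(self) -> bool:
        return False


def _f3pl(x, b, c, e):
    return c + (1.0 - c) / (1.0 + np.exp(b * (np.log(x) - np.log(e))))


def fit_3pl(
    concs,
    viabilities,
    rmse_max: float = RMSE_MAX,
    min_points: int = MIN_POINTS,
) -> CurveFit3PL | RejectedFit:
    """Fit the 3PL viability curve by constrained nonlinear least squares.

    Constraints: c in [0, 1], b > 0, e > 0.  Three starts are tried
    (c0 in {min viability, 0}, b0 = 1, e0 = geometric mean of the
    concentrations; plus a steeper-slope start) and the best is kept.
    Returns :class:`RejectedFit` when fewer than ``min_points`` points are
    available, when optimization fails, or when the residual RMSE exceeds
    ``rmse_max`` (curves above 0.3 are conventionally considered
    unreliable).
    """
    x = np.asarray(concs, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if x.shape != v.shape:
        raise ValueError("concs and viabilities must have equal length")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("concentrations must be strictly positive and finite")
    if len(x) < min_points:
        return RejectedFit("min_points", n_points=len(x))

    logx = np.log(x)
    degenerate = float(np.ptp(v)) < 1e-9

    def residuals(theta):
        b, c, loge = theta
        return c + (1.0 - c) / (1.0 + np.exp(b * (logx - loge))) - v

    e0 = float(np.exp(logx.mean()))  # geometric mean of doses
    starts = [
        (1.0, float(v.min()), np.log(e0)),
        (1.0, 0.0, np.log(e0)),
        (3.0, float(v.min()), np.log(e0)),
    ]
    lb = [1e-6, 0.0, np.log(1e-12)]
    ub = [50.0, 1.0, np.log(1e12)]
    best = None
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return RejectedFit("optim_failure", n_points=len(x))
    b, c, loge = best.x
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    if rmse > rmse_max:
        return RejectedFit("rmse", n_points=len(x), rmse=rmse)
    return CurveFit3PL(
        b=float(b), c=float(c), e=float(np.exp(loge)), rmse=rmse,
        n_points=len(x), degenerate_flat=degenerate,
    )


def curve_eval(fit: CurveFit3PL, x):
    """Evaluate the fitted curve; x = 0 returns the limit value 1."""
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("concentration must be finite")
    with np.errstate(divide="ignore"):
        out = np.where(arr > 0, _f3pl(np.maximum(arr, 1e-300), fit.b, fit.c, fit.e), 1.0)
    return float(out) if arr.ndim == 0 else out


def ic_level(fit: CurveFit3PL, inhibition_level: float) -> float | None:
    """Concentration where the curve reaches a given inhibition level.

    ``inhibition_level`` is in percent (50 for IC50, 25 for IC75's
    complement, etc.); the target viability is (100 - level)/100.  Returns
    None (undefined) when the lower asymptote never reaches that line.
    Closed-form inversion: x = e * ((1-c)/(v*-c) - 1)^(1/b).
    """
    if not 0 < inhibition_level < 100:
        raise ValueError("inhibition_level must be in (0, 100)")
    v_star = (100.0 - inhibition_level) / 100.0
    if fit.c >= v_star:
        return None
    gap = (1.0 - fit.c) / (v_star - fit.c) - 1.0
    if gap <= 0:  # v* above the upper asymptote: never crossed either
        return None
    return float(fit.e * gap ** (1.0 / fit.b))


def cmax_viability(
    fit: CurveFit3PL, cmax: float, max_screened_conc: float | None = None
) -> tuple[float, bool]:
    """Viability at the drug's CMax concentration, from the fitted curve.

    Returns ``(viability, extrapolated)`` where ``extrapolated`` is True
    when CMax exceeds the highest screened concentration, i.e. the curve is
    being read outside the measured range.
    """
    if cmax <= 0:
        raise ValueError("cmax must be positive")
    extrapolated = max_screened_conc is not None and cmax > max_screened_conc
    return float(curve_eval(fit, cmax)), extrapolated


@dataclass
class DoseResponseMatrix:
    """Grid of viabilities over two drugs' concentrations, with 0 margins."""

    cell_line: str
    drug_a: str
    drug_b: str
    row_concs: np.ndarray   # sorted µM concentrations for drug A, includes 0
    col_concs: np.ndarray   # sorted µM concentrations for drug B, includes 0
    viability: np.ndarray   # rows x cols, NaN where unobserved
    missing: np.ndarray     # bool mask of unobserved cells

    @property
    def complete(self) -> bool:
        return not self.missing.any()


def assemble_matrix(
    entries: pd.DataFrame, cell_line: str, drug_a: str, drug_b: str
) -> DoseResponseMatrix:
    """Build a dose-response matrix for one cell line and drug pair.

    ``entries`` uses the screen-table schema with concentrations in raw µM
    and must contain only rows for this cell line involving drugs A and/or
    B: combination rows fill the interior, monotherapy rows fill the
    zero-dose margins, and (0, 0) is set to viability 1 (untreated).
    Cells without data are NaN and flagged in ``missing``.
    """
    df = entries
    if (df["cell_line"] != cell_line).any():
        raise ValueError("entries span more than one cell line")

    def viab(inh):
        return inhibition_to_viability(float(inh))

    points: dict[tuple[float, float], float] = {}
    for row in df.itertuples(index=False):
        dcol = None if (row.drug_col is None or (isinstance(row.drug_col, float) and np.isnan(row.drug_col))) else row.drug_col
        if dcol is None:
            if row.drug_row == drug_a:
                key = (float(row.conc_row), 0.0)
            elif row.drug_row == drug_b:
                key = (0.0, float(row.conc_row))
            else:
                raise ValueError(f"monotherapy drug {row.drug_row!r} not in pair")
        else:
            pair = {row.drug_row: float(row.conc_row), dcol: float(row.conc_col)}
            if set(pair) != {drug_a, drug_b}:
                raise ValueError(f"combination {set(pair)} does not match pair")
            key = (pair[drug_a], pair[drug_b])
        if key in points and not np.isclose(points[key], viab(row.inhibition)):
            raise ValueError(f"conflicting duplicate measurement at {key}")
        points[key] = viab(row.inhibition)

    row_concs = np.array(sorted({0.0} | {a for a, _ in points}))
    col_concs = np.array(sorted({0.0} | {b for _, b in points}))
    viability = np.full((len(row_concs), len(col_concs)), np.nan)
    for (a, b), v in points.items():
        viability[np.searchsorted(row_concs, a), np.searchsorted(col_concs, b)] = v
    viability[0, 0] = 1.0  # untreated control
    missing = np.isnan(viability)
    return DoseResponseMatrix(
        cell_line=cell_line, drug_a=drug_a, drug_b=drug_b,
        row_concs=row_concs, col_concs=col_concs,
        viability=viability, missing=missing,
    )


def combination_cmax_viability(
    matrix: DoseResponseMatrix,
    cmax_a: float,
    cmax_b: float,
    grid_n: int = 100,
    clamp: bool = True,
) -> tuple[float, bool]:
    """Minimum interpolated viability over the CMax box of a dose matrix.

    The interval [0, CMax] of each drug is divided into ``grid_n`` equally
    spaced concentrations (inclusive of both endpoints) and the viability
    at each of the grid_n x grid_n dose combinations is obtained by
    bilinear interpolation from the matrix; the minimum of those values is
    returned, together with a flag indicating whether the box had to be
    clamped to the screened concentration range.  Matrix-based measures
    never extrapolate: with ``clamp=False`` a CMax beyond the screened
    range raises instead.
    """
    if cmax_a <= 0 or cmax_b <= 0:
        raise ValueError("CMax concentrations must be positive")
    hi_a, hi_b = float(matrix.row_concs[-1]), float(matrix.col_concs[-1])
    clamped = cmax_a > hi_a or cmax_b > hi_b
    if clamped and not clamp:
        raise ValueError(
            f"CMax box ({cmax_a}, {cmax_b}) exceeds screened range ({hi_a}, {hi_b})"
        )
    box_a, box_b = min(cmax_a, hi_a), min(cmax_b, hi_b)
    inside = (matrix.row_concs <= box_a)[:, None] & (matrix.col_concs <= box_b)[None, :]
    if matrix.missing[inside].any():
        raise ValueError("matrix has missing cells inside the CMax box")
    interp = RegularGridInterpolator(
        (matrix.row_concs, matrix.col_concs),
        np.nan_to_num(matrix.viability, nan=1.0),
        method="linear", bounds_error=True,
    )
    ga = np.linspace(0.0, box_a, grid_n)
    gb = np.linspace(0.0, box_b, grid_n)
    aa, bb = np.meshgrid(ga, gb, indexing="ij")
    vals = interp(np.column_stack([aa.ravel(), bb.ravel()]))
    return float(vals.min()), clamped


def curve_rmse_report(fits) -> dict | None:
    """Summary of fit quality: mean RMSE and fraction below the 0.3 gate."""
    rmses = np.array([f.rmse for f in fits if isinstance(f, CurveFit3PL)])
    if rmses.size == 0:
        return None
    return {
        "mean_rmse": float(rmses.mean()),
        "fraction_below_0.3": float(np.mean(rmses < RMSE_MAX)),
        "n_curves": int(rmses.size),
    }
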