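"""Four-parameter log-logistic dose-response fitting, R^2 scoring and ranking.

Each peptide's replicate-level log2 quantities are fitted against compound
concentration with the 4PL (LL.4-family) model

    f(d) = bottom + (top - bottom) / (1 + (EC50 / d)^slope)

where ``bottom`` is the asymptote at zero dose, ``top`` the asymptote at
infinite dose, ``EC50`` the midpoint concentration and ``slope`` a Hill-type
steepness.  The vehicle point (d = 0) is evaluated through the analytic limit
f(0) = bottom (slope > 0), so no pseudo-dose is needed.  Fitting is
least-squares on log2 intensities with log10(EC50) as the free parameter,
multi-start over log-spaced EC50 guesses; peptides are then ranked by the
coefficient of determination R^2 of the fit, the statistic used to pick the
binding-site peptides, with low EC50 breaking ties (peptides closest to a
binding event show both high R^2 and low EC50).

``top - bottom`` is unconstrained in sign because limited proteolysis can
either increase or decrease a peptide's yield on ligand binding; the slope is
constrained positive and the direction is carried by the asymptote difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .doses import DoseSeries

_LN10 = math.log(10.0)

#: optimizer stops: relative change tolerances and evaluation cap per start
FIT_FTOL = 1e-10
FIT_XTOL = 1e-12
MAX_NFEV = 60
N_STARTS = 5

#: log10(EC50) is bounded to the dose range widened by two decades each side
EC50_BOUND_DECADES = 2.0
#: Hill-type slopes of proteolytic dose responses sit near 1; the bound
#: keeps the optimizer out of the step-function regime
SLOPE_BOUNDS = (1e-2, 10.0)


def four_pl(dose, bottom: float, top: float, ec50: float, slope: float):
    """Evaluate the 4PL model at ``dose`` (scalar or array, molar).

    ``dose == 0`` returns ``bottom`` exactly (the analytic limit for
    slope > 0), so the vehicle control is always usable.
    """
    if ec50 <= 0:
        raise ValueError(f"ec50 must be positive, got {ec50}")
    scalar = np.isscalar(dose) or np.ndim(dose) == 0
    dose_arr = np.atleast_1d(np.asarray(dose, dtype=float))
    out = np.full(dose_arr.shape, float(bottom))
    pos = dose_arr > 0
    with np.errstate(over="ignore"):
        u = (ec50 / dose_arr[pos]) ** slope
    out[pos] = bottom + (top - bottom) / (1.0 + u)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class DoseResponseFit:
    """Result of fitting one peptide's dose-response curve."""

    peptide: str
    bottom: float
    top: float
    ec50: float
    slope: float
    r_squared: float
    n_points: int
    converged: bool
    degenerate: bool

    @property
    def rankable(self) -> bool:
        return self.converged and not self.degenerate


def _sigmoid_basis(doses: np.ndarray, log_ec50: float, slope: float) -> np.ndarray:
    """s(d) = 1 / (1 + (EC50/d)^slope), with s(0) = 0 (the analytic limit)."""
    s = np.zeros(doses.shape)
    posm = doses > 0
    with np.errstate(over="ignore"):
        u = (10.0 ** log_ec50 / doses[posm]) ** slope
    s[posm] = 1.0 / (1.0 + u)
    return s


def _solve_asymptotes(s: np.ndarray, y: np.ndarray):
    """Exact least-squares (bottom, top) for fixed sigmoid basis s:
    f = bottom*(1-s) + top*s.  2x2 normal equations; falls back to the mean
    when the basis is degenerate (s constant)."""
    a = 1.0 - s
    aa, as_, ss_ = a @ a, a @ s, s @ s
    det = aa * ss_ - as_ * as_
    if det <= 1e-14 * max(aa, ss_, 1.0):
        m = y.mean()
        return np.array([m, m])
    ay, sy = a @ y, s @ y
    bottom = (ss_ * ay - as_ * sy) / det
    top = (aa * sy - as_ * ay) / det
    return np.array([bottom, top])


def _fit_arrays(doses: np.ndarray, y: np.ndarray):
    """Core least-squares fit of (bottom, top, log10 EC50, slope) to
    replicate-level points; returns (params, ss_res, converged).

    Variable projection: for fixed (log10 EC50, slope) the model is linear
    in (bottom, top) through f = bottom*(1-s) + top*s, so the asymptotes
    are solved exactly and only the two nonlinear parameters are searched.
    The search is a dense vectorized grid over (log10 EC50, slope) followed
    by a local least-squares polish from the best grid point of each of
    N_STARTS log10(EC50) bands (multi-start over the dose range).
    """
    pos = doses[doses > 0]
    lo, hi = math.log10(pos.min()), math.log10(pos.max())
    bound_lo = [lo - EC50_BOUND_DECADES, SLOPE_BOUNDS[0]]
    bound_hi = [hi + EC50_BOUND_DECADES, SLOPE_BOUNDS[1]]

    # --- vectorized grid scan -------------------------------------------
    grid_L = np.linspace(bound_lo[0], bound_hi[0], 8 * N_STARTS)
    grid_h = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    LL, HH = np.meshgrid(grid_L, grid_h, indexing="ij")
    phi_grid = np.column_stack([LL.ravel(), HH.ravel()])
    posm = doses > 0
    with np.errstate(over="ignore"):
        u = (10.0 ** phi_grid[:, :1] / doses[posm][None, :]) ** phi_grid[:, 1:2]
    S = np.zeros((phi_grid.shape[0], doses.size))
    S[:, posm] = 1.0 / (1.0 + u)
    A1 = 1.0 - S
    aa = (A1 * A1).sum(axis=1)
    as_ = (A1 * S).sum(axis=1)
    ss_ = (S * S).sum(axis=1)
    ay = A1 @ y
    sy = S @ y
    det = aa * ss_ - as_ * as_
    safe = det > 1e-14 * np.maximum.reduce([aa, ss_, np.ones_like(aa)])
    bottom_g = np.where(safe, (ss_ * ay - as_ * sy) / np.where(safe, det, 1.0), y.mean())
    top_g = np.where(safe, (aa * sy - as_ * ay) / np.where(safe, det, 1.0), y.mean())
    resid = bottom_g[:, None] * A1 + top_g[:, None] * S - y[None, :]
    ss_grid = (resid * resid).sum(axis=1)

    def residuals(phi):
        s = _sigmoid_basis(doses, phi[0], phi[1])
        beta = _solve_asymptotes(s, y)
        return beta[0] * (1.0 - s) + beta[1] * s - y

    # --- local polish from the best grid point of each EC50 band ---------
    bands = np.array_split(np.arange(grid_L.size), N_STARTS)
    best = None
    for band in bands:
        idx_band = np.array([i * grid_h.size + j for i in band for j in range(grid_h.size)])
        start = phi_grid[idx_band[np.argmin(ss_grid[idx_band])]]
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(bound_lo, bound_hi),
                ftol=FIT_FTOL,
                xtol=FIT_XTOL,
                gtol=FIT_FTOL,
                max_nfev=MAX_NFEV,
            )
        except Exception:
            continue
        ss = float(2.0 * res.cost)
        if best is None or ss < best[1]:
            best = (res.x, ss, bool(res.success))
    if best is None:
        return None
    phi, ss, converged = best
    s = _sigmoid_basis(doses, phi[0], phi[1])
    bottom, top = _solve_asymptotes(s, y)
    params = np.array([bottom, top, phi[0], phi[1]])
    return params, ss, converged


def fit_peptide(
    quant: pd.DataFrame,
    peptide: str,
    dose_series: DoseSeries | None = None,
    value_column: str = "log2_centered",
    min_doses: int = 5,
) -> DoseResponseFit:
    """Fit the 4PL model to one peptide's replicate-level quantities.

    Parameters
    ----------
    quant
        PeptideQuantTable with a median-centered log2 column (see
        :func:`lipsite.differential.median_center`); raw ``quantity`` is
        log2-transformed on the fly if the centered column is absent.
    peptide
        ``modified_sequence`` to fit.
    dose_series
        Optional; only used to sanity-check dose coverage.
    min_doses
        Fewer distinct doses than this (vehicle included) gives a degenerate
        fit, not an exception.

    Notes
    -----
    R^2 is computed on the replicate-level points, not dose means, so
    replicate scatter counts against the fit.  ``degenerate`` is set when
    the response is constant (zero total sum of squares) or no start
    converges.
    """
    rows = quant[quant["modified_sequence"] == peptide]
    if value_column in rows.columns:
        y = rows[value_column].to_numpy(dtype=float)
    else:
        y = np.log2(rows["quantity"].to_numpy(dtype=float))
    doses = rows["dose"].to_numpy(dtype=float)
    n_points = y.size

    def degenerate_fit(converged=False):
        return DoseResponseFit(
            peptide, float("nan"), float("nan"), float("nan"), float("nan"),
            float("-inf"), n_points, converged, True,
        )

    if n_points == 0 or np.unique(doses).size < min_doses or not (doses == 0).any():
        return degenerate_fit()
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return degenerate_fit(converged=True)

    best = _fit_arrays(doses, y)
    if best is None:
        return degenerate_fit()
    (b, t, log_ec50, slope), ss_res, converged = best
    r2 = 1.0 - ss_res / ss_tot
    return DoseResponseFit(
        peptide=peptide,
        bottom=float(b),
        top=float(t),
        ec50=float(10.0 ** log_ec50),
        slope=float(slope),
        r_squared=float(r2),
        n_points=int(n_points),
        converged=converged,
        degenerate=not converged,
    )


def fit_all(
    quant: pd.DataFrame,
    peptides=None,
    dose_series: DoseSeries | None = None,
    value_column: str = "log2_centered",
) -> list[DoseResponseFit]:
    """Fit every requested peptide (default: all in the table)."""
    if peptides is None:
        peptides = quant["modified_sequence"].unique()
    return [
        fit_peptide(quant, p, dose_series, value_column=value_column)
        for p in peptides
    ]


def rank_peptides(
    fits: list[DoseResponseFit], r2_threshold: float = 0.9
) -> list[tuple[DoseResponseFit, bool]]:
    """Order non-degenerate fits by R^2 descending; ties broken by lower EC50
    then lexicographic peptide sequence.

    Returns ``(fit, above_threshold)`` pairs; fits below ``r2_threshold``
    stay in the ranking but are flagged False.
    """
    rankable = [f for f in fits if f.rankable]
    ordered = sorted(rankable, key=lambda f: (-f.r_squared, f.ec50, f.peptide))
    return [(f, f.r_squared > r2_threshold) for f in ordered]


@dataclass(frozen=True)
class TopSelection:
    """The top-k peptides by dose-response correlation."""

    fits: tuple[DoseResponseFit, ...]
    requested: int

    @property
    def complete(self) -> bool:
        return len(self.fits) >= self.requested

    @property
    def peptides(self) -> tuple[str, ...]:
        return tuple(f.peptide for f in self.fits)


def select_top(
    ranking: list[tuple[DoseResponseFit, bool]],
    k: int = 3,
    require_candidates: bool = False,
    candidates: set | None = None,
) -> TopSelection:
    """First ``k`` ranked fits, optionally restricted to the differential
    candidate set; if fewer than ``k`` are available all are returned and
    ``complete`` is False."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    pool = [f for f, _ in ranking]
    if require_candidates:
        if candidates is None:
            raise ValueError("require_candidates=True needs a candidate set")
        pool = [f for f in pool if f.peptide in candidates]
    return TopSelection(fits=tuple(pool[:k]), requested=k)


def fits_to_frame(ranking: list[tuple[DoseResponseFit, bool]]) -> pd.DataFrame:
    """Tabulate a ranking as a DataFrame sorted by rank."""
    return pd.DataFrame(
        {
            "peptide": [f.peptide for f, _ in ranking],
            "bottom": [f.bottom for f, _ in ranking],
            "top": [f.top for f, _ in ranking],
            "ec50_molar": [f.ec50 for f, _ in ranking],
            "slope": [f.slope for f, _ in ranking],
            "r_squared": [f.r_squared for f, _ in ranking],
            "n_points": [f.n_points for f, _ in ranking],
            "above_threshold": [flag for _, flag in ranking],
        }
    )
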