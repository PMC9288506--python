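"""Differential peptide screen: high doses vs vehicle, with FDR control.

Candidate peptides for dose-response fitting are those whose abundance
changes between the high-dose treatments and the vehicle control.  The
screen is: per-sample median-centering of log2 quantities, a two-sided
Welch t-test per modified peptide per comparison dose, Benjamini-Hochberg
q-values within each comparison, then the threshold filter
q < 0.01 and |log2FC| > 0.46 (either comparison passing suffices by
default; the combination rule is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default comparison doses (molar): the three concentrations above the
#: compound's estimated cellular IC50, each tested against vehicle
DEFAULT_COMPARISON_DOSES = (2e-6, 2e-5, 1e-4)
DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_FC_THRESHOLD = 0.46

#: variance / mean-difference below these are numerically zero (log2 scale)
_VAR_EPS = 1e-20
_MEAN_EPS = 1e-9


def median_center(quant: pd.DataFrame) -> pd.DataFrame:
    """Add a ``log2_centered`` column: log2(quantity) minus the per-sample
    (dose, replicate) median across peptides.

    Removes sample loading differences before any statistics; standard for
    global proteome runs.
    """
    out = quant.copy()
    log2q = np.log2(out["quantity"].to_numpy(dtype=float))
    out["log2_centered"] = log2q - pd.Series(log2q, index=out.index).groupby(
        [out["dose"], out["replicate"]]
    ).transform("median")
    return out


def log2_fold_change(
    quant: pd.DataFrame, peptide: str, dose: float, vehicle: float = 0.0
) -> float:
    """log2 fold-change of a peptide at ``dose`` vs ``vehicle``, computed as
    the difference of group means on the median-centered log2 scale.

    Returns NaN (missing-data marker, excluded downstream) when the peptide
    has no replicate at either condition.
    """
    table = quant if "log2_centered" in quant.columns else median_center(quant)
    rows = table[table["modified_sequence"] == peptide]
    a = rows.loc[rows["dose"] == dose, "log2_centered"].to_numpy(dtype=float)
    b = rows.loc[rows["dose"] == vehicle, "log2_centered"].to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    return float(a.mean() - b.mean())


def differential_test(
    quant: pd.DataFrame, peptide: str, dose: float, vehicle: float = 0.0
) -> float:
    """Two-sided Welch t-test p-value on median-centered log2 quantities.

    Degenerate groups: zero pooled variance with equal means gives p = 1
    (no evidence of change); zero variance with different means gives p = 0.
    Fewer than 2 replicates in either group returns NaN (missing-data
    marker).
    """
    table = quant if "log2_centered" in quant.columns else median_center(quant)
    rows = table[table["modified_sequence"] == peptide]
    a = rows.loc[rows["dose"] == dose, "log2_centered"].to_numpy(dtype=float)
    b = rows.loc[rows["dose"] == vehicle, "log2_centered"].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        return float("nan")
    # zero pooled variance up to numerical dust from the centering step
    if a.var(ddof=1) <= _VAR_EPS and b.var(ddof=1) <= _VAR_EPS:
        return 1.0 if abs(a.mean() - b.mean()) <= _MEAN_EPS else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, in [0, 1].

    NaN entries (missing-data markers) propagate as NaN and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


@dataclass(frozen=True)
class DifferentialResult:
    """One peptide x comparison row of the differential screen."""

    peptide: str
    dose: float
    log2_fc: float
    p_value: float
    q_value: float
    passes: bool


def differential_table(
    quant: pd.DataFrame,
    comparison_doses=DEFAULT_COMPARISON_DOSES,
    vehicle: float = 0.0,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_scope: str = "per_comparison",
) -> pd.DataFrame:
    """Run the full differential screen.

    Returns a DataFrame with one row per (peptide, comparison dose):
    columns peptide, dose, log2_fc, p_value, q_value, passes.  q-values are
    BH-adjusted within each comparison by default (``fdr_scope="global"``
    pools all comparisons into one family).
    """
    table = quant if "log2_centered" in quant.columns else median_center(quant)
    peptides = sorted(table["modified_sequence"].unique())

    # vectorized group moments per (peptide, dose): same Welch formulas as
    # differential_test, computed for all peptides at once
    grouped = table.groupby(["modified_sequence", "dose"])["log2_centered"].agg(
        ["mean", "var", "count"]
    )

    def moments(dose):
        sub = grouped.xs(dose, level="dose").reindex(peptides)
        return (
            sub["mean"].to_numpy(),
            sub["var"].to_numpy(),
            sub["count"].to_numpy(),
        )

    mv, vv, nv = moments(vehicle)
    frames = []
    for dose in comparison_doses:
        md, vd, nd = moments(dose)
        lfc = md - mv
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = vd / nd + vv / nv
            t = (md - mv) / np.sqrt(se2)
            df = se2**2 / ((vd / nd) ** 2 / (nd - 1) + (vv / nv) ** 2 / (nv - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        zero_var = (vd <= _VAR_EPS) & (vv <= _VAR_EPS)
        equal = np.abs(md - mv) <= _MEAN_EPS
        p = np.where(zero_var & equal, 1.0, p)
        p = np.where(zero_var & ~equal, 0.0, p)
        p = np.where((nd < 2) | (nv < 2), np.nan, p)
        p = np.where(np.isnan(md) | np.isnan(mv), np.nan, p)
        frames.append(
            pd.DataFrame(
                {"peptide": peptides, "dose": dose, "log2_fc": lfc, "p_value": p}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    if fdr_scope == "global":
        out["q_value"] = adjust_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = np.nan
        for dose in comparison_doses:
            mask = out["dose"] == dose
            out.loc[mask, "q_value"] = adjust_fdr(out.loc[mask, "p_value"].to_numpy())
    out["passes"] = (out["q_value"] < q_threshold) & (
        out["log2_fc"].abs() > fc_threshold
    )
    return out


def filter_candidates(
    results: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    rule: str = "any",
) -> set[str]:
    """Apply the candidate filter to a differential table.

    A peptide is a candidate iff, under ``rule="any"`` (default), at least
    one comparison passes both thresholds, or under ``rule="all"`` every
    comparison with data passes.
    """
    if rule not in {"any", "all"}:
        raise ValueError(f"rule must be 'any' or 'all', got {rule!r}")
    res = results.copy()
    res["ok"] = (res["q_value"] < q_threshold) & (res["log2_fc"].abs() > fc_threshold)
    grouped = res.dropna(subset=["p_value"]).groupby("peptide")["ok"]
    agg = grouped.any() if rule == "any" else grouped.all()
    return set(agg.index[agg])
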