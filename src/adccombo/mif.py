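"""Multiplexed-IF quantification: H-scores, (co-)positivity, and the
core -> tumor -> patient classification cascade.

Input is a per-cell table in which each segmented cell carries an ordinal
staining-intensity class per marker (0 = negative, 1 = weak, 2 = moderate,
3 = strong).  The H-score for a marker over a set of cells is

    H = 1 * pct_weak + 2 * pct_moderate + 3 * pct_strong        (0..300)

with percentages on the 0-100 scale.  A cell is *positive* for a marker when
its class is at least weak; co-positivity for a marker pair (and triple
positivity) requires positivity for every marker involved.  Core-level
metrics are averaged (unweighted) across a tumor's cores; a tumor is called
double-positive for a pair when its averaged co-positive fraction reaches the
threshold tau (default 0.20, inclusive).  Patient-level roll-ups count tumors
and patients positive per pair.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT, MARKERS, Thresholds

__all__ = [
    "EmptyInputError",
    "compute_h_score",
    "positive_fraction",
    "copositive_fraction",
    "triple_positive_fraction",
    "summarize_cores",
    "summarize_tumors",
    "classify_tumor_positive",
    "patient_rollup",
    "compare_phenotypes",
    "pairwise_rank_tests",
]


class EmptyInputError(ValueError):
    """Raised when a metric is requested over zero cells/cores."""


def _classes(cells: pd.DataFrame, marker: str) -> np.ndarray:
    col = f"{marker}_class"
    if col not in cells.columns:
        raise KeyError(f"no intensity-class column for marker {marker!r}")
    if len(cells) == 0:
        raise EmptyInputError("empty cell set")
    cls = cells[col].to_numpy()
    if not np.isin(cls, [0, 1, 2, 3]).all():
        raise ValueError(f"intensity classes for {marker} must be ordinal in 0..3")
    return cls


def compute_h_score(cells: pd.DataFrame, marker: str) -> float:
    """H-score in [0, 300]: intensity class weighted by percent of cells."""
    cls = _classes(cells, marker)
    return float(100.0 * cls.mean())   # == 1*pct_weak + 2*pct_mod + 3*pct_strong


def positive_fraction(cells: pd.DataFrame, marker: str) -> float:
    """Fraction of cells with at least weak staining."""
    return float((_classes(cells, marker) >= 1).mean())


def copositive_fraction(cells: pd.DataFrame, marker_a: str, marker_b: str) -> float:
    """Fraction of cells positive for both markers of a pair."""
    pos_a = _classes(cells, marker_a) >= 1
    pos_b = _classes(cells, marker_b) >= 1
    return float((pos_a & pos_b).mean())


def triple_positive_fraction(cells: pd.DataFrame, markers: Sequence[str] = MARKERS) -> float:
    """Fraction of cells positive for every marker listed."""
    pos = np.ones(len(cells), dtype=bool)
    for m in markers:
        pos &= _classes(cells, m) >= 1
    return float(pos.mean())


def _pair_cols(markers: Sequence[str]) -> list[tuple[str, str]]:
    return list(itertools.combinations(markers, 2))


def summarize_cores(cells: pd.DataFrame, markers: Sequence[str] = MARKERS) -> pd.DataFrame:
    """Per-core H-scores and (co-)positivity fractions.

    Returns one row per core with columns ``h_score_<m>``, ``pos_frac_<m>``,
    ``copos_<a>_<b>``, ``coneg_<a>_<b>``, ``triple_pos_frac`` and ``n_cells``,
    retaining the core's tumor/patient/phenotype annotation.
    """
    if len(cells) == 0:
        raise EmptyInputError("empty cell table")
    df = cells.copy()
    pos = {m: (df[f"{m}_class"] >= 1) for m in markers}
    agg: dict[str, pd.Series] = {}
    for m in markers:
        agg[f"h_score_{m}"] = 100.0 * df[f"{m}_class"].astype(float)
        agg[f"pos_frac_{m}"] = pos[m].astype(float)
    for a, b in _pair_cols(markers):
        agg[f"copos_{a}_{b}"] = (pos[a] & pos[b]).astype(float)
        agg[f"coneg_{a}_{b}"] = (~pos[a] & ~pos[b]).astype(float)
    agg["triple_pos_frac"] = np.logical_and.reduce([pos[m] for m in markers]).astype(float)
    metrics = pd.DataFrame(agg, index=df.index)
    keys = [c for c in ("core_id", "tumor_id", "patient_id", "phenotype") if c in df.columns]
    grouped = metrics.groupby(df["core_id"], sort=False).mean()
    grouped["n_cells"] = df.groupby("core_id", sort=False).size()
    meta = df[keys].drop_duplicates("core_id").set_index("core_id")
    out = meta.join(grouped).reset_index()
    return out


def summarize_tumors(
    core_summary: pd.DataFrame,
    tau: float = DEFAULT.tau,
    markers: Sequence[str] = MARKERS,
) -> pd.DataFrame:
    """Average core metrics per tumor (unweighted) and flag pair positivity.

    The double-positive call applies the threshold tau to the core-averaged
    co-positive fraction; per-core fractions stay available in the core table
    for intra-tumoral heterogeneity.
    """
    if len(core_summary) == 0:
        raise EmptyInputError("empty core summary")
    metric_cols = [c for c in core_summary.columns
                   if c.startswith(("h_score_", "pos_frac_", "copos_", "coneg_", "triple_"))]
    keys = [c for c in ("tumor_id", "patient_id", "phenotype") if c in core_summary.columns]
    means = core_summary.groupby("tumor_id", sort=False)[metric_cols].mean()
    means["n_cores"] = core_summary.groupby("tumor_id", sort=False).size()
    meta = core_summary[keys].drop_duplicates("tumor_id").set_index("tumor_id")
    out = meta.join(means).reset_index()
    for a, b in _pair_cols(markers):
        out[f"positive_{a}_{b}"] = classify_tumor_positive(out[f"copos_{a}_{b}"], tau)
    return out


def classify_tumor_positive(copositive_fraction, tau: float = DEFAULT.tau):
    """Double-positive call: co-positive fraction >= tau (inclusive boundary)."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0,1), got {tau}")
    frac = np.asarray(copositive_fraction, dtype=float)
    out = frac >= tau
    return bool(out) if out.ndim == 0 else out


def _pct(count: int, total: int) -> float:
    """Cohort percentage, rounded to one decimal for reporting."""
    return round(100.0 * count / total, 1) if total else float("nan")


def patient_rollup(
    tumor_summary: pd.DataFrame,
    markers: Sequence[str] = MARKERS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level and cohort-level positivity counts per marker pair.

    Returns
    -------
    patients : DataFrame
        Per patient and pair: number of tumors, number positive, whether any
        tumor is positive and whether all are.
    cohort : DataFrame
        Per pair: tumor counts and percentages cohort-wide and within each
        phenotype, plus patient counts (>=1 positive tumor; all tumors
        positive) with percentages.  Percentages are rounded to one decimal.
    """
    if len(tumor_summary) == 0:
        raise EmptyInputError("empty tumor summary")
    pairs = _pair_cols(markers)
    pat_rows = []
    for pid, grp in tumor_summary.groupby("patient_id", sort=False):
        row = {"patient_id": pid, "n_tumors": len(grp)}
        for a, b in pairs:
            npos = int(grp[f"positive_{a}_{b}"].sum())
            row[f"n_positive_{a}_{b}"] = npos
            row[f"any_positive_{a}_{b}"] = npos >= 1
            row[f"all_positive_{a}_{b}"] = npos == len(grp)
        pat_rows.append(row)
    patients = pd.DataFrame(pat_rows)

    n_tumors = len(tumor_summary)
    n_patients = len(patients)
    cohort_rows = []
    for a, b in pairs:
        flag = tumor_summary[f"positive_{a}_{b}"]
        row = {
            "pair": f"{a}_{b}",
            "n_tumors": n_tumors,
            "n_positive_tumors": int(flag.sum()),
            "pct_positive_tumors": _pct(int(flag.sum()), n_tumors),
            "n_patients": n_patients,
            "n_patients_any_positive": int(patients[f"any_positive_{a}_{b}"].sum()),
            "pct_patients_any_positive": _pct(int(patients[f"any_positive_{a}_{b}"].sum()), n_patients),
            "n_patients_all_positive": int(patients[f"all_positive_{a}_{b}"].sum()),
            "pct_patients_all_positive": _pct(int(patients[f"all_positive_{a}_{b}"].sum()), n_patients),
        }
        if "phenotype" in tumor_summary.columns:
            for pheno, grp in tumor_summary.groupby("phenotype", sort=False):
                npos = int(grp[f"positive_{a}_{b}"].sum())
                row[f"n_tumors[{pheno}]"] = len(grp)
                row[f"n_positive[{pheno}]"] = npos
                row[f"pct_positive[{pheno}]"] = _pct(npos, len(grp))
        cohort_rows.append(row)
    return patients, pd.DataFrame(cohort_rows)


# ---------------------------------------------------------------------------
# phenotype comparisons
# ---------------------------------------------------------------------------

def _rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p.

    Exact enumeration when the combined sample size is small and there are no
    ties; otherwise the normal approximation with midrank tie correction.
    """
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pairwise_rank_tests(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    holm: bool = True,
) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests with Holm step-down adjustment."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        x, y = values[groups == ga], values[groups == gb]
        if len(x) == 0 or len(y) == 0:
            raise ValueError(f"group {ga if len(x) == 0 else gb} has zero observations")
        rows.append({"group_a": ga, "group_b": gb, "n_a": len(x), "n_b": len(y),
                     "median_a": float(np.median(x)), "median_b": float(np.median(y)),
                     "p_raw": _rank_sum_p(x, y)})
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def compare_phenotypes(
    tumor_summary: pd.DataFrame,
    value_col: str,
    group_col: str = "phenotype",
) -> pd.DataFrame:
    """Compare a tumor-level metric (e.g. an averaged H-score) across
    phenotypes with Holm-adjusted pairwise rank-sum tests."""
    df = tumor_summary.dropna(subset=[value_col, group_col])
    out = pairwise_rank_tests(df[value_col], df[group_col])
    out.insert(0, "metric", value_col)
    return out
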