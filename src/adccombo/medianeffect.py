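"""Chou–Talalay median-effect fitting and combination-index analysis.

The median-effect equation relates dose D to fraction affected fa through

    fa / (1 - fa) = (D / Dm)^m

so log10(fa/(1-fa)) is linear in log10(D) with slope m (sigmoidicity) and the
median-effect dose Dm = 10^(-intercept/m) — the dose producing 50% effect.
Fitting is ordinary least squares on that line; r is the correlation
coefficient of the linearized fit.  Fractions affected are clipped to
[epsilon, 1-epsilon] before the logit transform (points at 0 or 1 carry no
information on that scale) and points whose raw fa falls outside (0, 1) after
clipping are dropped.

For a combination tested at a constant dose ratio, the combination index at a
given effect level fa is

    CI(fa) = d1 / Dx1(fa) + d2 / Dx2(fa)          (mutually exclusive form)

where (d1, d2) are the component doses in the combination achieving fa and
Dxj(fa) = Dmj * (fa/(1-fa))^(1/mj) is the dose of drug j alone producing the
same fa.  CI < 1 indicates synergy, CI = 1 additivity, CI > 1 antagonism.
The non-exclusive form adds the cross term d1*d2 / (Dx1*Dx2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT

__all__ = [
    "MedianEffectModel",
    "MedianEffectResults",
    "CIResult",
    "combination_index",
    "classify_synergy",
]


class InsufficientDataError(ValueError):
    """Fewer than two informative dose-response points."""


@dataclass
class MedianEffectResults:
    """Parameters of a fitted median-effect model for one agent or one
    fixed-ratio combination."""

    m: float                  # sigmoidicity (slope of the median-effect plot)
    dm: float                 # median-effect dose, units of the input doses
    r: float                  # correlation coefficient of the linearized fit
    n_points: int
    label: str = "agent"
    cytotoxic: bool = True    # False flags m <= 0 (no dose-dependent kill)
    model: "MedianEffectModel | None" = field(default=None, repr=False)

    def fa(self, dose):
        """Predicted fraction affected at the given dose(s)."""
        r = (np.asarray(dose, dtype=float) / self.dm) ** self.m
        out = r / (1.0 + r)
        return float(out) if out.ndim == 0 else out

    def dose_for_effect(self, fa):
        """Dx: dose producing fraction affected fa, Dm*(fa/(1-fa))^(1/m)."""
        fa = np.asarray(fa, dtype=float)
        if np.any((fa <= 0) | (fa >= 1)):
            raise ValueError("fa must lie strictly inside (0, 1)")
        out = self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)
        return float(out) if out.ndim == 0 else out

    def summary(self) -> str:
        flag = "" if self.cytotoxic else "  [warning: m <= 0, non-cytotoxic fit]"
        return (f"median-effect fit [{self.label}]: m={self.m:.4g}, Dm={self.dm:.4g}, "
                f"r={self.r:.4f}, n={self.n_points}{flag}")

    def plot(self, ax=None):
        """Median-effect plot: observed logits and the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            ax.scatter(np.log10(self.model.dose_), self.model.logit_, s=18, label="observed")
        xs = np.linspace(np.log10(self.dm) - 2, np.log10(self.dm) + 2, 50)
        ax.plot(xs, self.m * xs - self.m * np.log10(self.dm), label="fit")
        ax.set_xlabel("log10 dose")
        ax.set_ylabel("log10 fa/(1-fa)")
        ax.set_title(self.summary())
        ax.legend()
        return ax


class MedianEffectModel:
    """Median-effect model for one dose-response series.

    Parameters
    ----------
    dose, fa : array-like
        Doses (> 0) and fractions affected.  Replicates are passed as repeated
        dose values; the fit operates on all points.
    epsilon : clipping bound for fa before the logit transform.
    """

    def __init__(self, dose, fa, epsilon: float = DEFAULT.epsilon, label: str = "agent"):
        dose = np.asarray(dose, dtype=float)
        fa = np.asarray(fa, dtype=float)
        if dose.shape != fa.shape:
            raise ValueError("dose and fa must have the same length")
        if np.any(dose <= 0):
            raise ValueError("doses must be positive")
        keep = np.isfinite(fa) & (fa > 0.0) & (fa < 1.0)
        fa = np.clip(fa, epsilon, 1.0 - epsilon)
        self.label = label
        self.epsilon = epsilon
        self.dose_ = dose[keep]
        self.fa_ = fa[keep]
        self.logit_ = np.log10(self.fa_ / (1.0 - self.fa_))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        dose_col: str = "dose",
        viability_col: str = "viability",
        epsilon: float = DEFAULT.epsilon,
        label: str | None = None,
    ) -> "MedianEffectModel":
        """Build from a tidy table with dose and relative-viability columns
        (fa = 1 - viability)."""
        if label is None:
            label = str(df["agent"].iloc[0]) if "agent" in df.columns else "agent"
        return cls(df[dose_col], 1.0 - df[viability_col].to_numpy(), epsilon=epsilon, label=label)

    def fit(self) -> MedianEffectResults:
        if len(self.dose_) < 2 or len(np.unique(self.dose_)) < 2:
            raise InsufficientDataError(
                f"{self.label}: need >= 2 informative points inside (0, 1), "
                f"got {len(self.dose_)}"
            )
        x = np.log10(self.dose_)
        res = stats.linregress(x, self.logit_)
        m = float(res.slope)
        dm = float(10.0 ** (-res.intercept / m)) if m != 0 else np.inf
        return MedianEffectResults(
            m=m, dm=dm, r=float(res.rvalue), n_points=len(self.dose_),
            label=self.label, cytotoxic=m > 0, model=self,
        )


def classify_synergy(ci_summary: float, band: float = DEFAULT.ci_additive_band) -> str:
    """Chou–Talalay call: CI < 1 synergy, CI > 1 antagonism, with values
    within ``band`` of 1 reported as additive."""
    if ci_summary <= 0:
        raise ValueError("combination index must be positive")
    if abs(ci_summary - 1.0) <= band:
        return "additive"
    return "synergistic" if ci_summary < 1.0 else "antagonistic"


@dataclass
class CIResult:
    """Combination-index profile for one drug pair."""

    pair: str
    fa_grid: np.ndarray          # achieved fa at the combination points
    ci: np.ndarray               # CI at each achieved fa
    ci_at_ed50: float            # CI at fa = 0.5 from the constant-ratio fit
    ci_mean: float               # mean CI over the achieved-fa grid
    classification: str
    form: str = "exclusive"
    combo_fit: MedianEffectResults | None = field(default=None, repr=False)

    @property
    def ci_summary(self) -> float:
        return self.ci_at_ed50

    def summary(self) -> str:
        return (f"combination index [{self.pair}] ({self.form}): CI(ED50)={self.ci_at_ed50:.3f}, "
                f"mean CI={self.ci_mean:.3f} over {len(self.fa_grid)} points -> {self.classification}")


def _ci_at(fa, dx_total_1, dx_total_2, fit_a, fit_b, form):
    ci = dx_total_1 / fit_a.dose_for_effect(fa) + dx_total_2 / fit_b.dose_for_effect(fa)
    if form == "nonexclusive":
        ci = ci + (dx_total_1 * dx_total_2) / (
            fit_a.dose_for_effect(fa) * fit_b.dose_for_effect(fa)
        )
    return ci


def combination_index(
    fit_a: MedianEffectResults,
    fit_b: MedianEffectResults,
    combo: pd.DataFrame,
    epsilon: float = DEFAULT.epsilon,
    form: str = "exclusive",
    band: float = DEFAULT.ci_additive_band,
) -> CIResult:
    """Combination index for a constant-ratio combination series.

    Parameters
    ----------
    fit_a, fit_b : single-agent median-effect fits.
    combo : DataFrame with columns ``dose`` (drug A component), ``partner_dose``
        (drug B component) and ``viability`` (relative viability of the
        combination well).
    form : "exclusive" (default, no cross term) or "nonexclusive".

    The per-point CI uses each point's achieved fa with its actual component
    doses.  The ED50 summary refits the median-effect model to the combination
    on total dose and evaluates CI at fa = 0.5 via the fixed component ratio.
    """
    if form not in ("exclusive", "nonexclusive"):
        raise ValueError("form must be 'exclusive' or 'nonexclusive'")
    for need in ("dose", "partner_dose", "viability"):
        if need not in combo.columns:
            raise ValueError(f"combination table lacks column {need!r}")
    d1 = combo["dose"].to_numpy(dtype=float)
    d2 = combo["partner_dose"].to_numpy(dtype=float)
    fa = 1.0 - combo["viability"].to_numpy(dtype=float)
    keep = np.isfinite(fa) & (fa > 0.0) & (fa < 1.0)
    if not keep.any():
        raise InsufficientDataError("no combination point has fa inside (0, 1)")
    d1, d2 = d1[keep], d2[keep]
    fa = np.clip(fa[keep], epsilon, 1.0 - epsilon)

    ci_points = _ci_at(fa, d1, d2, fit_a, fit_b, form)

    # constant-ratio ED50 summary
    total = d1 + d2
    w1 = d1 / total
    if np.ptp(w1) > 1e-6:
        raise ValueError("combination is not constant-ratio; ED50 summary undefined")
    combo_fit = MedianEffectModel(total, fa, epsilon=epsilon,
                                  label=f"{fit_a.label}+{fit_b.label}").fit()
    d_total_50 = combo_fit.dose_for_effect(0.5)
    ci_50 = float(_ci_at(0.5, w1[0] * d_total_50, (1 - w1[0]) * d_total_50,
                         fit_a, fit_b, form))

    order = np.argsort(fa)
    return CIResult(
        pair=f"{fit_a.label}+{fit_b.label}",
        fa_grid=fa[order],
        ci=np.asarray(ci_points)[order],
        ci_at_ed50=ci_50,
        ci_mean=float(np.mean(ci_points)),
        classification=classify_synergy(ci_50, band=band),
        form=form,
        combo_fit=combo_fit,
    )
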