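"""Longitudinal xenograft tumor-growth modeling.

Volumes are modeled on the natural-log scale with a linear mixed model

    log V_it = (b0 + u_i) + b_g * day_t + group main effects + eps_it

i.e. fixed effects for day, treatment group and their interaction, and a
random intercept u_i per animal (REML).  The per-group slope b_g is the daily
log growth rate; back-transformed it reports as a daily percentage growth
rate 100*(exp(b_g) - 1).  Group contrasts are computed on the slope scale
(Wald inference) and translated to percentage-point differences per day.

A noise-free design (zero residual variance) makes the REML likelihood
degenerate; in that case the model falls back to an exact least-squares fit
with animal fixed effects, which recovers the generating slopes exactly with
zero-width intervals.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TumorGrowthModel", "GrowthResults"]


class DegenerateDesignError(ValueError):
    """Design cannot identify slopes (e.g. a group with < 2 timepoints)."""


@dataclass
class GrowthResults:
    """Fitted growth rates, contrasts and variance components."""

    groups: list[str]
    slopes: pd.DataFrame          # per group: slope, se, ci_low, ci_high, daily pct columns
    contrasts: pd.DataFrame       # per group pair: slope diff, CI, p, pct-point diff
    animal_sd: float
    residual_sd: float
    reference: str
    n_animals: int
    n_obs: int
    model: "TumorGrowthModel | None" = field(default=None, repr=False)

    @property
    def daily_growth_pct(self) -> pd.Series:
        return self.slopes.set_index("group")["daily_growth_pct"]

    def summary(self) -> str:
        lines = [
            f"Tumor growth model: {self.n_obs} observations, {self.n_animals} animals, "
            f"reference group {self.reference!r}",
            f"variance components: animal intercept SD={self.animal_sd:.4g}, "
            f"residual SD={self.residual_sd:.4g}",
            "",
            self.slopes.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            "",
            self.contrasts.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def report(self) -> pd.DataFrame:
        """Reporting table with growth rates as whole-percent ranges.

        Each group's daily growth is formatted from its 95% CI bounds rounded
        to whole percentage points ("9-10% per day"), matching the convention
        of reporting a rate range; contrasts likewise.
        """
        rows = []
        for _, r in self.slopes.iterrows():
            lo, hi = round(r["daily_pct_ci_low"]), round(r["daily_pct_ci_high"])
            rng = f"{lo:g}%" if lo == hi else f"{lo:g}-{hi:g}%"
            rows.append({"group": r["group"], "daily_growth": f"{rng} per day",
                         "daily_growth_pct": r["daily_growth_pct"]})
        rep = pd.DataFrame(rows)
        con = []
        for _, r in self.contrasts.iterrows():
            lo, hi = sorted((abs(round(r["pct_diff_ci_low"])), abs(round(r["pct_diff_ci_high"]))))
            rng = f"{hi:g}%" if lo == hi else f"{lo:g}-{hi:g}%"
            con.append({"contrast": f"{r['group_a']} vs {r['group_b']}",
                        "daily_rate_change": rng, "p_value": r["p_value"]})
        return rep, pd.DataFrame(con)

    def plot(self, ax=None):
        """Spaghetti plot of log-volume trajectories with fitted group lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.data if self.model is not None else None
        if df is not None:
            for (_, g), grp in df.groupby(["animal_id", "group"], sort=False):
                ax.plot(grp["day"], np.log(grp["volume_mm3"]), alpha=0.25, lw=0.8)
        ax.set_xlabel("day")
        ax.set_ylabel("log volume (mm3)")
        return ax


class TumorGrowthModel:
    """Mixed-effects exponential growth model for a longitudinal volume table.

    Parameters
    ----------
    data : long-format DataFrame with columns animal_id, group, day,
        volume_mm3 (positive).
    reference : reference treatment group; defaults to "vehicle" when present,
        otherwise the first group by appearance.
    """

    def __init__(self, data: pd.DataFrame, reference: str | None = None):
        need = {"animal_id", "group", "day", "volume_mm3"}
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"growth table lacks columns {sorted(missing)}")
        if np.any(data["volume_mm3"].to_numpy(dtype=float) <= 0):
            raise ValueError("volumes must be positive")
        per_group = data.groupby("group")["day"].nunique()
        if (per_group < 2).any():
            bad = per_group[per_group < 2].index.tolist()
            raise DegenerateDesignError(f"groups with < 2 timepoints: {bad}")
        if (data.groupby("animal_id")["group"].nunique() > 1).any():
            raise ValueError("each animal must belong to exactly one group")
        self.data = data.copy()
        self.data["log_volume"] = np.log(self.data["volume_mm3"].astype(float))
        groups = list(pd.unique(self.data["group"]))
        if reference is None:
            reference = "vehicle" if "vehicle" in groups else groups[0]
        if reference not in groups:
            raise ValueError(f"reference group {reference!r} not present")
        self.reference = reference
        self.groups = [reference] + [g for g in groups if g != reference]

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, reference: str | None = None) -> "TumorGrowthModel":
        return cls(data, reference=reference)

    # -- internals ----------------------------------------------------------

    def _exact_fit(self) -> GrowthResults:
        """Least squares with animal fixed effects for noise-free designs."""
        rows, cons = [], []
        slopes = {}
        for g in self.groups:
            sub = self.data[self.data["group"] == g]
            # within-animal slope is exact under zero residual noise
            b = np.polyfit(sub["day"], sub["log_volume"], 1)[0] if sub["animal_id"].nunique() == 1 \
                else self._pooled_within_slope(sub)
            slopes[g] = b
            pct = 100.0 * np.expm1(b)
            rows.append({"group": g, "slope": b, "se": 0.0, "ci_low": b, "ci_high": b,
                         "daily_growth_pct": pct, "daily_pct_ci_low": pct, "daily_pct_ci_high": pct})
        for ga, gb in itertools.combinations(self.groups, 2):
            d = slopes[ga] - slopes[gb]
            pctd = 100.0 * (np.exp(slopes[ga]) - np.exp(slopes[gb]))
            cons.append({"group_a": ga, "group_b": gb, "slope_diff": d, "se": 0.0,
                         "ci_low": d, "ci_high": d, "p_value": 1.0 if d == 0 else 0.0,
                         "pct_diff": pctd, "pct_diff_ci_low": pctd, "pct_diff_ci_high": pctd})
        return GrowthResults(
            groups=self.groups, slopes=pd.DataFrame(rows), contrasts=pd.DataFrame(cons),
            animal_sd=float(self.data.groupby("animal_id")["log_volume"].first().std() or 0.0),
            residual_sd=0.0, reference=self.reference,
            n_animals=self.data["animal_id"].nunique(), n_obs=len(self.data), model=self,
        )

    @staticmethod
    def _pooled_within_slope(sub: pd.DataFrame) -> float:
        x = sub["day"].to_numpy(dtype=float)
        y = sub["log_volume"].to_numpy(dtype=float)
        xc = x - sub.groupby("animal_id")["day"].transform("mean").to_numpy()
        yc = y - sub.groupby("animal_id")["log_volume"].transform("mean").to_numpy()
        return float(np.dot(xc, yc) / np.dot(xc, xc))

    def _residual_scale(self) -> float:
        """Residual SD after removing per-animal linear trends (cheap check)."""
        res = []
        for _, grp in self.data.groupby("animal_id"):
            if grp["day"].nunique() < 2:
                continue
            coef = np.polyfit(grp["day"], grp["log_volume"], 1)
            res.extend(grp["log_volume"] - np.polyval(coef, grp["day"]))
        return float(np.std(res)) if res else 0.0

    # -- fitting ------------------------------------------------------------

    def fit(self, reml: bool = True, alpha: float = 0.05) -> GrowthResults:
        """REML mixed-model fit; falls back to exact LS when noise-free."""
        if self._residual_scale() < 1e-10:
            return self._exact_fit()

        import statsmodels.formula.api as smf

        data = self.data.copy()
        data["group"] = pd.Categorical(data["group"], categories=self.groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("log_volume ~ day * group", data=data, groups=data["animal_id"])
            mr = md.fit(reml=reml)

        params = mr.fe_params
        cov = mr.cov_params().loc[params.index, params.index]
        zc = stats.norm.ppf(1.0 - alpha / 2.0)

        # linear-combination vector for each group's slope
        vecs = {}
        for g in self.groups:
            v = pd.Series(0.0, index=params.index)
            v["day"] = 1.0
            inter = f"day:group[T.{g}]"
            if inter in v.index:
                v[inter] = 1.0
            vecs[g] = v

        rows = []
        for g in self.groups:
            v = vecs[g]
            b = float(v @ params)
            se = float(np.sqrt(v @ cov @ v))
            lo, hi = b - zc * se, b + zc * se
            rows.append({"group": g, "slope": b, "se": se, "ci_low": lo, "ci_high": hi,
                         "daily_growth_pct": 100.0 * np.expm1(b),
                         "daily_pct_ci_low": 100.0 * np.expm1(lo),
                         "daily_pct_ci_high": 100.0 * np.expm1(hi)})
        slopes = pd.DataFrame(rows)

        cons = []
        for ga, gb in itertools.combinations(self.groups, 2):
            v = vecs[ga] - vecs[gb]
            d = float(v @ params)
            se = float(np.sqrt(v @ cov @ v))
            lo, hi = d - zc * se, d + zc * se
            z = d / se if se > 0 else np.inf * np.sign(d)
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else (1.0 if d == 0 else 0.0)
            b_ref = float(vecs[gb] @ params)
            # percentage-point difference per day, anchored at the comparator slope
            cons.append({"group_a": ga, "group_b": gb, "slope_diff": d, "se": se,
                         "ci_low": lo, "ci_high": hi, "p_value": p,
                         "pct_diff": 100.0 * (np.exp(b_ref + d) - np.exp(b_ref)),
                         "pct_diff_ci_low": 100.0 * (np.exp(b_ref + lo) - np.exp(b_ref)),
                         "pct_diff_ci_high": 100.0 * (np.exp(b_ref + hi) - np.exp(b_ref))})
        contrasts = pd.DataFrame(cons)

        return GrowthResults(
            groups=self.groups, slopes=slopes, contrasts=contrasts,
            animal_sd=float(np.sqrt(max(float(mr.cov_re.iloc[0, 0]), 0.0))),
            residual_sd=float(np.sqrt(mr.scale)),
            reference=self.reference,
            n_animals=self.data["animal_id"].nunique(), n_obs=len(self.data), model=self,
        )
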