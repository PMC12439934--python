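"""Discordant-positivity heterogeneity indices with clustered bootstrap CIs.

A *unit* is either a patient (its samples are the tumor-level co-positive
fractions at its metastatic sites: intra-patient heterogeneity) or a tumor
(its samples are the core-level fractions: intra-tumoral heterogeneity).
Within a unit, an unordered pair of samples is *discordant* when exactly one
of the two reaches the double-positive threshold tau (>= tau on the positive
side, strictly below on the other).  A unit's heterogeneity index is the
fraction of its sample pairs that are discordant; units with fewer than two
samples carry no pairs and are excluded as non-informative.

The pooled point estimate is the arithmetic mean of per-unit indices over
informative units (optionally a pair-weighted pool), and the 95% confidence
interval is a percentile bootstrap that resamples whole units with
replacement, respecting the clustering of samples within patients/tumors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT

__all__ = [
    "HeterogeneityResult",
    "HeterogeneityIndexModel",
    "pair_discordance",
    "heterogeneity_index",
    "pooled_index_with_bootstrap",
    "heterogeneity_table",
]


def pair_discordance(fa: float, fb: float, tau: float = DEFAULT.tau) -> int:
    """1 if exactly one of the two fractions reaches tau (inclusive), else 0."""
    if not (0 <= fa <= 1 and 0 <= fb <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    return int((fa >= tau) != (fb >= tau))


def heterogeneity_index(samples: Sequence[float], tau: float = DEFAULT.tau) -> float:
    """Fraction of discordant unordered sample pairs within one unit.

    With k positives among n samples there are k*(n-k) discordant pairs out of
    n*(n-1)/2, so the index equals 2*k*(n-k) / (n*(n-1)).
    """
    s = np.asarray(samples, dtype=float)
    if len(s) < 2:
        raise ValueError("a unit needs >= 2 samples to form pairs")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    pos = s >= tau
    k, n = int(pos.sum()), len(s)
    return 2.0 * k * (n - k) / (n * (n - 1))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Pooled heterogeneity index with a clustered percentile-bootstrap CI."""

    level: str                 # "intra_patient" | "intra_tumoral" | free label
    pair: str
    point_estimate: float
    ci_low: float
    ci_high: float
    n_units: int               # informative units (>= 2 samples)
    n_informative_pairs: int   # total unordered pairs across informative units
    n_boot: int
    seed: int | None
    weighting: str = "unit"

    def __post_init__(self) -> None:
        assert 0.0 <= self.point_estimate <= 1.0
        assert self.ci_low <= self.point_estimate <= self.ci_high

    def summary(self) -> str:
        return (f"{self.level} heterogeneity [{self.pair}]: "
                f"{self.point_estimate:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f}; "
                f"{self.n_units} units, {self.n_informative_pairs} pairs, B={self.n_boot})")


class HeterogeneityIndexModel:
    """Estimator for the pooled discordance index over clustered units.

    Parameters
    ----------
    units : mapping of unit id -> sequence of co-positive fractions
    tau : double-positive threshold applied to each fraction
    weighting : "unit" (equal weight per informative unit, default) or "pair"
        (pool all pairs so larger units weigh more)
    """

    def __init__(
        self,
        units: Mapping[str, Sequence[float]],
        tau: float = DEFAULT.tau,
        weighting: str = "unit",
    ) -> None:
        if weighting not in ("unit", "pair"):
            raise ValueError("weighting must be 'unit' or 'pair'")
        self.tau = tau
        self.weighting = weighting
        self.unit_ids: list[str] = []
        self._indices: list[float] = []
        self._n_pairs: list[int] = []
        for uid, samples in units.items():
            s = np.asarray(samples, dtype=float)
            if len(s) < 2:
                continue   # non-informative: no pairs
            self.unit_ids.append(uid)
            self._indices.append(heterogeneity_index(s, tau))
            self._n_pairs.append(len(s) * (len(s) - 1) // 2)
        if not self.unit_ids:
            raise ValueError("no informative units (every unit has < 2 samples)")
        self.unit_indices = np.array(self._indices)
        self.unit_pairs = np.array(self._n_pairs)

    def _pool(self, idx: np.ndarray) -> float:
        if self.weighting == "pair":
            w = self.unit_pairs[idx]
            return float(np.sum(self.unit_indices[idx] * w) / np.sum(w))
        return float(np.mean(self.unit_indices[idx]))

    def fit(
        self,
        n_boot: int = DEFAULT.n_boot,
        seed: int | None = 0,
        level: str = "pooled",
        pair: str = "",
        ci_level: float = 0.95,
    ) -> HeterogeneityResult:
        """Point estimate plus percentile bootstrap CI over unit resamples."""
        if n_boot < 200:
            raise ValueError("use at least 200 bootstrap replicates")
        n = len(self.unit_ids)
        all_idx = np.arange(n)
        point = self._pool(all_idx)
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            boot[b] = self._pool(rng.integers(0, n, size=n))
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        # percentile CI can exclude the point estimate in degenerate resamples;
        # widen to bracket it so the interval is always interpretable
        lo, hi = min(float(lo), point), max(float(hi), point)
        return HeterogeneityResult(
            level=level, pair=pair, point_estimate=point, ci_low=lo, ci_high=hi,
            n_units=n, n_informative_pairs=int(self.unit_pairs.sum()),
            n_boot=n_boot, seed=seed, weighting=self.weighting,
        )


def pooled_index_with_bootstrap(
    units: Mapping[str, Sequence[float]],
    tau: float = DEFAULT.tau,
    n_boot: int = DEFAULT.n_boot,
    level: str = "pooled",
    seed: int | None = 0,
    weighting: str = "unit",
) -> HeterogeneityResult:
    """Convenience wrapper: build the model and fit in one call."""
    return HeterogeneityIndexModel(units, tau=tau, weighting=weighting).fit(
        n_boot=n_boot, seed=seed, level=level
    )


def _units_from_table(df: pd.DataFrame, unit_col: str, value_col: str) -> dict[str, np.ndarray]:
    return {uid: grp[value_col].to_numpy() for uid, grp in df.groupby(unit_col, sort=False)}


def heterogeneity_table(
    tumor_summary: pd.DataFrame,
    core_summary: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    tau: float = DEFAULT.tau,
    n_boot: int = DEFAULT.n_boot,
    seed: int | None = 0,
    weighting: str = "unit",
) -> pd.DataFrame:
    """Intra-patient (tumors within patient) and intra-tumoral (cores within
    tumor) heterogeneity for every marker pair, as one tidy table."""
    rows = []
    for a, b in pairs:
        col = f"copos_{a}_{b}"
        for level, df, unit_col in (
            ("intra_patient", tumor_summary, "patient_id"),
            ("intra_tumoral", core_summary, "tumor_id"),
        ):
            units = _units_from_table(df, unit_col, col)
            units = {k: v for k, v in units.items() if len(v) >= 2}
            if not units:
                continue
            res = HeterogeneityIndexModel(units, tau=tau, weighting=weighting).fit(
                n_boot=n_boot, seed=seed, level=level, pair=f"{a}_{b}"
            )
            rows.append({
                "level": res.level, "pair": res.pair, "estimate": res.point_estimate,
                "ci_low": res.ci_low, "ci_high": res.ci_high, "n_units": res.n_units,
                "n_informative_pairs": res.n_informative_pairs, "B": res.n_boot,
                "seed": res.seed, "weighting": res.weighting,
            })
    return pd.DataFrame(rows)
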