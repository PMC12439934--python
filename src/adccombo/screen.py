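"""Payload-screen normalization and synergy nomination.

Raw 384-well luminescence is anchored to the on-plate controls: relative
viability v = (RLU - mean positive control) / (mean vehicle - mean positive
control), clipped to [0, 1], and fraction affected e = 1 - v.  Replicate
wells are averaged after normalization.  A candidate synergistic pair must
(i) combine agents from different pharmacological subgroups and (ii) show a
Bliss excess

    excess = e_combo - (e1 + e2 - e1*e2)

of at least delta (default 0.10) in at least ``min_lines`` cell lines;
candidates are ranked by the excess summed over qualifying lines.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT
from .simulate import bliss_expected

__all__ = ["normalize_plate", "combine_effects", "nominate_pairs"]


class DegenerateControlsError(ValueError):
    """Vehicle mean does not exceed positive-control mean."""


def normalize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Control-anchored normalization of one cell line's plate.

    Parameters
    ----------
    plate : well table with columns agent1, agent2, dose_level, control, rlu
        (and optionally cell_line).

    Returns
    -------
    DataFrame with one row per (agent1, agent2, dose_level): mean fraction
    affected ``effect``, mean relative viability, mean log10 RLU and the
    number of wells averaged.
    """
    for need in ("control", "rlu"):
        if need not in plate.columns:
            raise ValueError(f"plate table lacks column {need!r}")
    if np.any(plate["rlu"].to_numpy() <= 0):
        raise ValueError("RLU values must be positive")
    veh = plate.loc[plate["control"] == "vehicle", "rlu"]
    pos = plate.loc[plate["control"] == "positive", "rlu"]
    if len(veh) < 3 or len(pos) < 3:
        raise ValueError("need >= 3 vehicle and >= 3 positive-control wells")
    mu_veh, mu_pos = float(veh.mean()), float(pos.mean())
    if mu_veh <= mu_pos:
        raise DegenerateControlsError(
            f"vehicle mean ({mu_veh:.3g}) must exceed positive-control mean ({mu_pos:.3g})"
        )
    treated = plate[plate["control"] == "none"].copy()
    v = np.clip((treated["rlu"] - mu_pos) / (mu_veh - mu_pos), 0.0, 1.0)
    treated["viability"] = v
    treated["log10_rlu"] = np.log10(treated["rlu"])
    grouped = (
        treated.groupby(["agent1", "agent2", "dose_level"], dropna=False, sort=False)
        .agg(viability=("viability", "mean"), log10_rlu=("log10_rlu", "mean"),
             n_wells=("rlu", "size"))
        .reset_index()
    )
    grouped["effect"] = 1.0 - grouped["viability"]
    if "cell_line" in plate.columns:
        grouped.insert(0, "cell_line", plate["cell_line"].iloc[0])
    return grouped


def combine_effects(plates: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Normalize every line's plate and stack into one effect table."""
    frames = []
    for line, plate in plates.items():
        eff = normalize_plate(plate)
        if "cell_line" not in eff.columns:
            eff.insert(0, "cell_line", line)
        frames.append(eff)
    return pd.concat(frames, ignore_index=True)


def _single_effect(singles: pd.DataFrame, line: str, agent: str, dose_level: str) -> float:
    sel = singles[(singles["cell_line"] == line) & (singles["agent1"] == agent)
                  & (singles["dose_level"] == dose_level)]
    if len(sel) == 0:
        raise ValueError(
            f"missing single-agent effect for {agent!r} ({dose_level}) in line {line!r}"
        )
    return float(sel["effect"].iloc[0])


def nominate_pairs(
    effects: pd.DataFrame,
    panel: pd.DataFrame,
    delta: float = DEFAULT.delta,
    min_lines: int = DEFAULT.min_lines,
    require_distinct_subgroup: bool = True,
) -> pd.DataFrame:
    """Nominate candidate synergistic pairs across cell lines.

    Parameters
    ----------
    effects : stacked output of :func:`combine_effects` over >= min_lines lines.
    panel : agent annotation with columns agent, moa_class, subgroup.
    delta : minimum Bliss excess per line on the fraction-affected scale.
    min_lines : lines in which the excess must reach delta.

    Returns the per-pair table (one row per pair, excess per line, count of
    qualifying lines, nomination flag) ranked by summed excess over
    qualifying lines.
    """
    sub = panel.set_index("agent")["subgroup"]
    moa = panel.set_index("agent")["moa_class"]
    singles = effects[effects["agent2"].isna()]
    combos = effects[effects["agent2"].notna()]
    rows = []
    for (a, b), grp in combos.groupby(["agent1", "agent2"], sort=False):
        row: dict = {"agent1": a, "agent2": b,
                     "moa_1": moa.get(a), "moa_2": moa.get(b),
                     "subgroup_1": sub.get(a), "subgroup_2": sub.get(b)}
        excesses = {}
        for _, r in grp.iterrows():
            line = r["cell_line"]
            e1 = _single_effect(singles, line, a, r["dose_level"])
            e2 = _single_effect(singles, line, b, r["dose_level"])
            excesses[line] = float(r["effect"] - bliss_expected(e1, e2))
        for line, x in excesses.items():
            row[f"excess[{line}]"] = x
        over = [x for x in excesses.values() if x >= delta]
        row["n_lines_over"] = len(over)
        row["summed_excess"] = float(np.sum(over)) if over else 0.0
        distinct = sub.get(a) != sub.get(b)
        row["distinct_subgroup"] = distinct
        row["nominated"] = (len(over) >= min_lines) and (distinct or not require_distinct_subgroup)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(["nominated", "summed_excess"], ascending=[False, False],
                           kind="stable").reset_index(drop=True)
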