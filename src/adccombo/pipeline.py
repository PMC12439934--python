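"""End-to-end orchestration: synthesize -> quantify -> heterogeneity ->
screen/synergy -> growth, from one config, with a manifest for reproducibility.

All I/O is plain CSV (plus a JSON manifest and optional YAML run config); a
rerun with the same config and seed produces bit-identical outputs for
synthetic inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import DEFAULT, MARKER_PAIRS, MARKERS, Thresholds
from .growth import TumorGrowthModel
from .heterogeneity import heterogeneity_table
from .medianeffect import MedianEffectModel, combination_index
from .mif import compare_phenotypes, patient_rollup, summarize_cores, summarize_tumors
from .screen import combine_effects, nominate_pairs
from .simulate import (
    GrowthSimConfig,
    MifSimConfig,
    ScreenSimConfig,
    gen_combo_dose_response,
    gen_dose_response,
    gen_growth_study,
    gen_mif_dataset,
    gen_screen_plate,
)

log = logging.getLogger("adccombo")

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """One-config description of a full synthetic pipeline run."""

    outdir: str | Path = "adccombo_run"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    mif: MifSimConfig | None = None
    screen: ScreenSimConfig | None = None
    growth: GrowthSimConfig | None = None
    cells_path: str | None = None       # alternative to synthesizing mIF data
    volumes_path: str | None = None     # alternative to synthesizing growth data

    def __post_init__(self) -> None:
        if self.mif is not None and self.cells_path is not None:
            raise ValueError("provide either an mIF synthesis config or a cells path, not both")
        if self.growth is not None and self.volumes_path is not None:
            raise ValueError("provide either a growth synthesis config or a volumes path, not both")


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage and write outputs + manifest to ``outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    manifest: dict = {
        "package_version": __version__,
        "seed": int(config.seed),
        "thresholds": th.__dict__,
        "outputs": {},
    }

    # --- mIF stage ---------------------------------------------------------
    mif_cfg = config.mif
    if mif_cfg is None and config.cells_path is None:
        mif_cfg = MifSimConfig(seed=int(seeds[0]))
    if config.cells_path is not None:
        cells = pd.read_csv(config.cells_path)
    else:
        cells, truth = _stage("simulate_mif")(gen_mif_dataset)(mif_cfg)
        _write(truth, outdir / "truth_mif.csv", manifest)
        _write(cells, outdir / "cells.csv", manifest)

    cores = _stage("mif_quant")(summarize_cores)(cells)
    tumors = summarize_tumors(cores, tau=th.tau)
    patients, cohort = patient_rollup(tumors)
    tests = pd.concat(
        [compare_phenotypes(tumors, f"h_score_{m}") for m in MARKERS], ignore_index=True
    )
    _write(cores, outdir / "core_summary.csv", manifest)
    _write(tumors, outdir / "tumor_summary.csv", manifest)
    _write(patients, outdir / "patient_summary.csv", manifest)
    _write(cohort, outdir / "cohort_rollup.csv", manifest)
    _write(tests, outdir / "phenotype_tests.csv", manifest)

    het = _stage("heterogeneity")(heterogeneity_table)(
        tumors, cores, MARKER_PAIRS, tau=th.tau, n_boot=th.n_boot, seed=int(seeds[1])
    )
    _write(het, outdir / "heterogeneity.csv", manifest)

    # --- screen stage ------------------------------------------------------
    screen_cfg = config.screen or ScreenSimConfig(
        seed=int(seeds[2]),
        interaction_map={("duocarmycin-TM", "A-1331852"): 0.25},
    )
    plates, screen_truth = _stage("simulate_screen")(gen_screen_plate)(screen_cfg)
    for line, plate in plates.items():
        safe = line.replace("/", "-")
        _write(plate, outdir / f"plate_{safe}.csv", manifest)
    _write(screen_truth, outdir / "truth_screen.csv", manifest)
    effects = _stage("normalize")(combine_effects)(plates)
    _write(effects, outdir / "effects.csv", manifest)
    noms = _stage("nominate")(nominate_pairs)(
        effects, screen_cfg.panel, delta=th.delta, min_lines=th.min_lines
    )
    _write(noms, outdir / "nominations.csv", manifest)

    # --- dose-response / combination-index stage ---------------------------
    doses = np.array([0.0625, 0.125, 0.25, 0.5, 1, 2, 4, 8, 16]) * 0.1
    pa, pb = (1.5, 0.08), (1.1, 0.25)   # (m, Dm) for the validated pair
    dr_a = gen_dose_response(*pa, doses, noise_cv=0.05, seed=int(seeds[3]),
                             n_replicates=3, agent="duocarmycin-TM")
    dr_b = gen_dose_response(*pb, doses, noise_cv=0.05, seed=int(seeds[4]),
                             n_replicates=3, agent="A-1331852")
    dr_ab = gen_combo_dose_response(pa, pb, doses, ratio=pb[1] / pa[1], excess=0.15,
                                    noise_cv=0.05, seed=int(seeds[5]), n_replicates=3,
                                    agent="duocarmycin-TM", partner_agent="A-1331852")
    dose_response = pd.concat([dr_a, dr_b, dr_ab], ignore_index=True)
    _write(dose_response, outdir / "dose_response.csv", manifest)

    fit_a = MedianEffectModel.from_dataframe(dr_a, epsilon=th.epsilon).fit()
    fit_b = MedianEffectModel.from_dataframe(dr_b, epsilon=th.epsilon).fit()
    fits = pd.DataFrame([
        {"agent": f.label, "m": f.m, "Dm": f.dm, "r": f.r, "n_points": f.n_points,
         "cytotoxic": f.cytotoxic}
        for f in (fit_a, fit_b)
    ])
    _write(fits, outdir / "medianeffect_fits.csv", manifest)
    ci = _stage("combination_index")(combination_index)(fit_a, fit_b, dr_ab,
                                                        epsilon=th.epsilon)
    ci_df = pd.DataFrame({"pair": ci.pair, "fa": ci.fa_grid, "ci": ci.ci,
                          "ci_at_ed50": ci.ci_at_ed50, "ci_mean": ci.ci_mean,
                          "classification": ci.classification, "form": ci.form})
    _write(ci_df, outdir / "ci_results.csv", manifest)

    # --- growth stage ------------------------------------------------------
    if config.volumes_path is not None:
        volumes = pd.read_csv(config.volumes_path)
    else:
        growth_cfg = config.growth or GrowthSimConfig(seed=int(seeds[6]))
        volumes, growth_truth = _stage("simulate_growth")(gen_growth_study)(growth_cfg)
        _write(growth_truth, outdir / "truth_growth.csv", manifest)
    _write(volumes, outdir / "volumes.csv", manifest)
    res = _stage("growth_fit")(TumorGrowthModel.from_dataframe(volumes).fit)()
    _write(res.slopes, outdir / "growth_fit.csv", manifest)
    _write(res.contrasts, outdir / "growth_contrasts.csv", manifest)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Schema, range, and referential-integrity checks with row diagnostics.

    ``tables`` may contain any of: cells, plate, dose_response, volumes.
    Returns a report DataFrame (table, check, status, n_failures, detail);
    never raises — failures are listed.
    """
    rows = []

    def add(table, check, bad_idx, detail=""):
        rows.append({"table": table, "check": check,
                     "status": "pass" if len(bad_idx) == 0 else "fail",
                     "n_failures": len(bad_idx),
                     "detail": detail if len(bad_idx) else "",
                     "rows": list(bad_idx[:10])})

    if "cells" in tables:
        c = tables["cells"]
        need = {"cell_id", "core_id", "tumor_id", "patient_id",
                *[f"{m}_class" for m in MARKERS]}
        missing = sorted(need - set(c.columns))
        add("cells", "schema", missing, f"missing columns {missing}")
        for m in MARKERS:
            col = f"{m}_class"
            if col in c.columns:
                bad = c.index[~c[col].isin([0, 1, 2, 3])]
                add("cells", f"range:{col}", bad, "class outside 0..3")
        if {"core_id", "tumor_id"} <= set(c.columns):
            multi = c.groupby("core_id")["tumor_id"].nunique()
            orphans = multi[multi > 1].index
            bad = c.index[c["core_id"].isin(orphans)]
            add("cells", "referential:core->tumor", bad, "core mapped to several tumors")
        if {"tumor_id", "patient_id"} <= set(c.columns):
            multi = c.groupby("tumor_id")["patient_id"].nunique()
            orphans = multi[multi > 1].index
            bad = c.index[c["tumor_id"].isin(orphans)]
            add("cells", "referential:tumor->patient", bad, "tumor mapped to several patients")

    if "plate" in tables:
        p = tables["plate"]
        need = {"agent1", "agent2", "dose_level", "control", "rlu"}
        missing = sorted(need - set(p.columns))
        add("plate", "schema", missing, f"missing columns {missing}")
        if "rlu" in p.columns:
            add("plate", "range:rlu", p.index[p["rlu"] <= 0], "non-positive RLU")
        if "control" in p.columns:
            for kind in ("vehicle", "positive"):
                n = int((p["control"] == kind).sum())
                add("plate", f"controls:{kind}", [] if n >= 3 else [-1],
                    f"only {n} {kind} wells (need >= 3)")
        if {"agent1", "agent2"} <= set(p.columns):
            singles = set(p.loc[p["agent2"].isna() & p["agent1"].notna(), "agent1"])
            combo_agents = set(p.loc[p["agent2"].notna(), "agent1"]) | set(
                p.loc[p["agent2"].notna(), "agent2"])
            bad_agents = combo_agents - singles
            bad = p.index[p["agent1"].isin(bad_agents) | p["agent2"].isin(bad_agents)]
            add("plate", "referential:pair->single", bad,
                f"combination agents without single wells: {sorted(bad_agents)}")

    if "dose_response" in tables:
        d = tables["dose_response"]
        need = {"agent", "dose", "viability"}
        missing = sorted(need - set(d.columns))
        add("dose_response", "schema", missing, f"missing columns {missing}")
        if "dose" in d.columns:
            add("dose_response", "range:dose", d.index[d["dose"] <= 0], "non-positive dose")

    if "volumes" in tables:
        v = tables["volumes"]
        need = {"animal_id", "group", "day", "volume_mm3"}
        missing = sorted(need - set(v.columns))
        add("volumes", "schema", missing, f"missing columns {missing}")
        if "volume_mm3" in v.columns:
            add("volumes", "range:volume", v.index[v["volume_mm3"] <= 0], "non-positive volume")
        if {"animal_id", "group"} <= set(v.columns):
            multi = v.groupby("animal_id")["group"].nunique()
            bad_animals = multi[multi > 1].index
            add("volumes", "referential:animal->group",
                v.index[v["animal_id"].isin(bad_animals)], "animal in several groups")

    return pd.DataFrame(rows)
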