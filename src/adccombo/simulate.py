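"""Synthetic-data generators with known ground truth.

Every pipeline stage (mIF quantification, heterogeneity, payload-synergy
screen, median-effect / combination-index analysis, xenograft growth model)
can be exercised end to end on data produced here, and each generator returns
the generating parameters alongside the data so downstream estimates have a
parameter-recovery oracle.

The generators emulate, at the level of the *classified tables* the pipeline
consumes:

* a tissue-microarray mIF study — per-cell ordinal staining classes
  (negative/weak/moderate/strong) for B7-H3, PSMA and STEAP1, organised as
  cells within cores within tumors within patients, with a tunable
  co-positivity coupling between markers;
* a 384-well payload screen — single agents at two working concentrations,
  all pairwise combinations of the combination subset at the low
  concentration, vehicle and positive-control wells, multiplicative
  luminescence noise;
* median-effect dose–response series for single agents and constant-ratio
  combinations, with optional Bliss-excess interaction as ground truth;
* exponential xenograft growth with per-animal lognormal intercepts.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning, so a fixed seed gives bit-identical tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import MARKERS, PHENOTYPES

__all__ = [
    "MifSimConfig",
    "ScreenSimConfig",
    "GrowthSimConfig",
    "default_marker_model",
    "default_agent_panel",
    "gen_mif_dataset",
    "gen_screen_plate",
    "gen_dose_response",
    "gen_combo_dose_response",
    "gen_growth_study",
    "median_effect_fa",
    "bliss_expected",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# shared small pieces
# ---------------------------------------------------------------------------

def median_effect_fa(dose: np.ndarray | float, m: float, dm: float) -> np.ndarray | float:
    """Fraction affected under the median-effect model fa = (D/Dm)^m / (1+(D/Dm)^m)."""
    r = (np.asarray(dose, dtype=float) / dm) ** m
    return r / (1.0 + r)


def bliss_expected(e1, e2):
    """Bliss-independence expected combined effect e1 + e2 - e1*e2."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if np.any((e1 < 0) | (e1 > 1) | (e2 < 0) | (e2 > 1)):
        raise ValueError("effects must lie in [0, 1]")
    out = e1 + e2 - e1 * e2
    if out.ndim == 0:
        return float(out)
    return out


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# mIF cohort
# ---------------------------------------------------------------------------

def default_marker_model() -> dict[str, dict[str, tuple[float, float, float, float]]]:
    """Per-phenotype class probabilities (negative, weak, moderate, strong).

    AR-active tumors retain PSMA/STEAP1 staining while neuroendocrine tumors
    largely lose it; B7-H3 stays detectable across phenotypes.  The per-cell
    class frequencies themselves are free parameters of the generator, chosen
    (together with the latent tumor/core effects) so the default cohort shows
    roughly one third of AR-active cells double-positive per pair and a
    middling fraction of tumors crossing the 20% double-positive threshold —
    the qualitative regime of a real mCRPC tissue-microarray cohort.
    """
    return {
        "AR+/NE-": {
            "b7h3": (0.52, 0.20, 0.16, 0.12),
            "psma": (0.56, 0.18, 0.15, 0.11),
            "steap1": (0.53, 0.19, 0.16, 0.12),
        },
        "AR+/NE+": {
            "b7h3": (0.55, 0.20, 0.15, 0.10),
            "psma": (0.65, 0.15, 0.12, 0.08),
            "steap1": (0.60, 0.18, 0.13, 0.09),
        },
        "AR-/NE-": {
            "b7h3": (0.60, 0.18, 0.13, 0.09),
            "psma": (0.85, 0.08, 0.05, 0.02),
            "steap1": (0.75, 0.12, 0.08, 0.05),
        },
        "AR-/NE+": {
            "b7h3": (0.65, 0.15, 0.12, 0.08),
            "psma": (0.92, 0.05, 0.02, 0.01),
            "steap1": (0.88, 0.07, 0.03, 0.02),
        },
    }


@dataclass
class MifSimConfig:
    """Design of a synthetic multiplexed-IF tissue-microarray cohort.

    ``tumor_effect_sd`` / ``core_effect_sd`` are the SDs of latent Gaussian
    shifts shared by all cells of a tumor / core; they create the
    between-tumor and between-core spread in staining fractions that drives
    tumor classification and heterogeneity indices in real cohorts.  Setting
    both to zero gives i.i.d. cells with the marker model's exact fractions.
    """

    n_patients: int = 58
    n_tumors_total: int | None = 176     # if None, tumors_per_patient is drawn per patient
    tumors_per_patient: int | tuple[int, int] = (1, 6)
    cores_per_tumor: int = 3
    cells_per_core: int = 200
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"AR+/NE-": 146 / 176, "AR+/NE+": 0.06, "AR-/NE-": 0.06,
                                 "AR-/NE+": 1 - 146 / 176 - 0.12}
    )
    marker_model: Mapping[str, Mapping[str, Sequence[float]]] = field(
        default_factory=default_marker_model
    )
    copositivity_coupling: float = 0.5
    patient_effect_sd: float = 0.40
    tumor_effect_sd: float = 0.30
    core_effect_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.patient_effect_sd, self.tumor_effect_sd, self.core_effect_sd) < 0:
            raise ConfigurationError("effect SDs must be non-negative")
        if self.n_patients < 1 or self.cores_per_tumor < 1 or self.cells_per_core < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.n_tumors_total is not None and self.n_tumors_total < self.n_patients:
            raise ConfigurationError("need at least one tumor per patient")
        mix = np.array([self.phenotype_mix.get(p, 0.0) for p in PHENOTYPES], dtype=float)
        if np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("phenotype_mix must be a probability vector over phenotypes")
        for pheno, model in self.marker_model.items():
            for marker in MARKERS:
                probs = np.asarray(model[marker], dtype=float)
                if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-8):
                    raise ConfigurationError(
                        f"class probabilities for {pheno}/{marker} must be a 4-vector summing to 1"
                    )
        # Equicorrelated 3-marker Gaussian copula is positive semi-definite only
        # for coupling >= -0.5; the pairwise-coupling parameterisation cannot
        # reach -1 jointly for three markers.
        if not -0.5 <= self.copositivity_coupling <= 1.0:
            raise ConfigurationError("copositivity_coupling must lie in [-0.5, 1.0] for three markers")


def _copula_root(rho: float, k: int) -> np.ndarray:
    """Matrix square root of the k x k equicorrelation matrix (PSD-safe)."""
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    lam, vec = np.linalg.eigh(corr)
    return vec * np.sqrt(np.clip(lam, 0.0, None))


def _orthant_upper(thresholds: np.ndarray, rho: float) -> np.ndarray:
    """P(Z_j > t_j for all j) for equicorrelated standard normals.

    ``thresholds`` has shape (n, k); returns n probabilities.  Degenerate
    couplings are handled in closed form (rho=0: product; rho=1: comonotone
    minimum); otherwise the symmetric MVN survival orthant equals the CDF at
    the negated thresholds.
    """
    t = np.atleast_2d(np.asarray(thresholds, dtype=float))
    marg = stats.norm.sf(t)
    if np.isclose(rho, 0.0):
        return marg.prod(axis=1)
    if np.isclose(rho, 1.0):
        return marg.min(axis=1)
    k = t.shape[1]
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    # fixed internal seed: the CDF quadrature is randomized quasi-Monte Carlo
    # and must not break run-to-run reproducibility of the truth table
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True, seed=0)
    out = np.atleast_1d(mvn.cdf(-t))
    return np.clip(out, 0.0, 1.0)


def _joint_positive_prob(neg_probs: Sequence[float], rho: float, shift: float = 0.0) -> float:
    """P(all markers positive) under the Gaussian copula with equicorrelation
    rho, given a latent mean shift shared by the markers."""
    a = np.asarray(neg_probs, dtype=float)
    t = stats.norm.ppf(a) - shift   # -inf when a == 0 is handled by sf
    return float(_orthant_upper(t[None, :], rho)[0])


def _tumor_allocation(cfg: MifSimConfig, rng: np.random.Generator) -> list[int]:
    """Tumor count per patient, honouring an exact cohort total when requested."""
    if cfg.n_tumors_total is not None:
        base = cfg.n_tumors_total // cfg.n_patients
        counts = np.full(cfg.n_patients, base, dtype=int)
        extra = cfg.n_tumors_total - base * cfg.n_patients
        counts[rng.choice(cfg.n_patients, size=extra, replace=False)] += 1
        return counts.tolist()
    if isinstance(cfg.tumors_per_patient, tuple):
        lo, hi = cfg.tumors_per_patient
        return rng.integers(lo, hi + 1, size=cfg.n_patients).tolist()
    return [int(cfg.tumors_per_patient)] * cfg.n_patients


def gen_mif_dataset(cfg: MifSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a per-cell mIF table and the per-tumor generating truth.

    Returns
    -------
    cells : DataFrame
        Columns cell_id, core_id, tumor_id, patient_id, phenotype and
        ``<marker>_class`` ordinal intensity classes (0=negative .. 3=strong).
    truth : DataFrame
        Per tumor: the exact generating marginal positive fractions, pairwise
        co-positive fractions and triple-positive fraction implied by the
        phenotype's marker model and the copula coupling.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    rho = cfg.copositivity_coupling
    root = _copula_root(rho, len(MARKERS))
    nm = len(MARKERS)

    # per-phenotype class cut points on the latent z scale: (marker, 3 cuts)
    cuts = {}
    for pheno in PHENOTYPES:
        model = cfg.marker_model[pheno]
        cum = np.stack([np.cumsum(np.asarray(model[m], dtype=float))[:3] for m in MARKERS])
        cuts[pheno] = stats.norm.ppf(np.clip(cum, 0.0, 1.0))

    tumor_counts = _tumor_allocation(cfg, rng)
    pheno_labels = list(PHENOTYPES)
    pheno_p = np.array([cfg.phenotype_mix.get(p, 0.0) for p in pheno_labels])

    n_core_cells = cfg.cells_per_core
    n_cells = cfg.cores_per_tumor * n_core_cells
    class_blocks: list[np.ndarray] = []
    core_ids: list[str] = []
    tumor_meta: list[tuple[str, str, str]] = []   # (tumor_id, patient_id, phenotype)
    core_truth: list[dict] = []
    for ip, n_tum in enumerate(tumor_counts):
        patient_id = f"P{ip + 1:03d}"
        b_patient = rng.normal(0.0, cfg.patient_effect_sd)
        for it in range(n_tum):
            tumor_id = f"{patient_id}-T{it + 1}"
            pheno = pheno_labels[rng.choice(len(pheno_labels), p=pheno_p)]
            tumor_meta.append((tumor_id, patient_id, pheno))
            b_tumor = b_patient + rng.normal(0.0, cfg.tumor_effect_sd)
            b_cores = b_tumor + rng.normal(0.0, cfg.core_effect_sd, size=cfg.cores_per_tumor)
            # latent Gaussian copula draw for all cells of this tumor at once
            if np.isclose(rho, 1.0):
                z = np.repeat(rng.standard_normal((n_cells, 1)), nm, axis=1)
            else:
                z = rng.standard_normal((n_cells, nm)) @ root.T
            shift = np.repeat(b_cores, n_core_cells)
            z = z + shift[:, None]
            classes = np.empty((n_cells, nm), dtype=np.int64)
            for j in range(nm):
                classes[:, j] = np.searchsorted(cuts[pheno][j], z[:, j], side="right")
            class_blocks.append(classes)
            neg_cut = cuts[pheno][:, 0]   # z cut below which a cell is negative
            for ic, b_c in enumerate(b_cores):
                core_ids.append(f"{tumor_id}-C{ic + 1}")
                t_eff = neg_cut - b_c
                entry = {"tumor_id": tumor_id}
                for j, m in enumerate(MARKERS):
                    entry[f"true_pos_{m}"] = float(stats.norm.sf(t_eff[j]))
                for (ja, ma), (jb, mb) in itertools.combinations(enumerate(MARKERS), 2):
                    entry[f"true_copos_{ma}_{mb}"] = float(
                        _orthant_upper(t_eff[[ja, jb]][None, :], rho)[0])
                entry["true_triple_pos"] = float(_orthant_upper(t_eff[None, :], rho)[0])
                core_truth.append(entry)

    all_classes = np.vstack(class_blocks)
    cells = pd.DataFrame({
        "cell_id": np.arange(1, all_classes.shape[0] + 1),
        "core_id": np.repeat(core_ids, n_core_cells),
        "tumor_id": np.repeat([t for t, _, _ in tumor_meta], n_cells),
        "patient_id": np.repeat([p for _, p, _ in tumor_meta], n_cells),
        "phenotype": np.repeat([ph for _, _, ph in tumor_meta], n_cells),
        **{f"{m}_class": all_classes[:, j] for j, m in enumerate(MARKERS)},
    })
    # a tumor's generating fraction is the mean of its cores' conditional
    # probabilities (cores contribute equal cell counts)
    truth = (pd.DataFrame(core_truth).groupby("tumor_id", sort=False).mean().reset_index())
    meta = pd.DataFrame(tumor_meta, columns=["tumor_id", "patient_id", "phenotype"])
    truth = meta.merge(truth, on="tumor_id")
    return cells, truth


# ---------------------------------------------------------------------------
# payload screen
# ---------------------------------------------------------------------------

_PANEL = [
    # agent, moa_class, subgroup, combination representative
    ("SN-38",          "DDD", "topo1",        True),
    ("exatecan",       "DDD", "topo1",        False),
    ("belotecan",      "DDD", "topo1",        False),
    ("PNU-159682",     "DDD", "topo2",        True),
    ("calicheamicin",  "DDD", "dna_scissor",  True),
    ("SG-3199",        "DDD", "crosslinker",  True),
    ("SJG-136",        "DDD", "crosslinker",  False),
    ("duocarmycin-TM", "DDD", "alkylator",    True),
    ("seco-DUBA",      "DDD", "alkylator",    False),
    ("MMAE",           "MDD", "auristatin",   True),
    ("MMAF",           "MDD", "auristatin",   False),
    ("MMAD",           "MDD", "auristatin",   False),
    ("DM1",            "MDD", "maytansinoid", True),
    ("DM4",            "MDD", "maytansinoid", False),
    ("eribulin",       "MDD", "eribulin",     True),
    ("tubulysin-M",    "MDD", "tubulysin",    True),
    ("thailanstatin-A", "ID", "splicing",     True),
    ("alpha-amanitin",  "ID", "rna_pol2",     True),
    ("FK866",           "ID", "nampt",        True),
    ("GNE-617",         "ID", "nampt",        False),
    ("A-1331852",       "ID", "bclxl",        True),
    ("WEHI-539",        "ID", "bclxl",        False),
    ("navitoclax",      "ID", "bclxl",        False),
]

DEFAULT_CELL_LINES = ("C4-2B", "22Rv1", "LuCaP176", "MSKCC-EF1")


def default_agent_panel() -> pd.DataFrame:
    """23-agent payload panel: class (DDD/MDD/ID), pharmacological subgroup,
    and whether the agent is the subgroup representative entering combinations."""
    return pd.DataFrame(_PANEL, columns=["agent", "moa_class", "subgroup", "combo_rep"])


@dataclass
class ScreenSimConfig:
    """Design of a synthetic 384-well payload screen."""

    cell_lines: Sequence[str] = DEFAULT_CELL_LINES
    panel: pd.DataFrame = field(default_factory=default_agent_panel)
    n_replicates: int = 3
    n_vehicle: int = 6
    n_positive: int = 6
    baseline_rlu: float = 1e6
    positive_effect: float = 1.0     # staurosporine at 1 uM: complete kill
    single_effects: pd.DataFrame | None = None   # columns: agent, cell_line, dose_level, effect
    interaction_map: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.05
    seed: int = 0

    @property
    def n_agents(self) -> int:
        return len(self.panel)

    @property
    def combo_agents(self) -> list[str]:
        return self.panel.loc[self.panel["combo_rep"], "agent"].tolist()

    @property
    def combo_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.combo_agents, 2))

    def __post_init__(self) -> None:
        k = len(self.combo_agents)
        assert len(self.combo_pairs) == k * (k - 1) // 2
        if self.n_vehicle < 3 or self.n_positive < 3:
            raise ConfigurationError("need >= 3 vehicle and >= 3 positive-control wells")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        combo = set(self.combo_agents)
        for a, b in self.interaction_map:
            if a not in combo or b not in combo:
                raise ConfigurationError(
                    f"interaction pair ({a}, {b}) names agents outside the combination subset"
                )
        if self.single_effects is not None:
            eff = self.single_effects["effect"].to_numpy()
            if np.any((eff < 0) | (eff > 1)):
                raise ConfigurationError("single effects must lie in [0, 1]")


def _draw_single_effects(cfg: ScreenSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Default per-agent per-line effects: low dose U(0.05, 0.6), high = low scaled up."""
    rows = []
    for line in cfg.cell_lines:
        low = rng.uniform(0.05, 0.60, size=cfg.n_agents)
        high = np.clip(low * rng.uniform(1.3, 2.0, size=cfg.n_agents), 0.0, 0.95)
        for agent, el, eh in zip(cfg.panel["agent"], low, high):
            rows.append({"agent": agent, "cell_line": line, "dose_level": "low", "effect": el})
            rows.append({"agent": agent, "cell_line": line, "dose_level": "high", "effect": eh})
    return pd.DataFrame(rows)


def gen_screen_plate(cfg: ScreenSimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate one 384-well screen plate per cell line.

    Each plate holds every single agent at the high and low working
    concentration, every pairwise combination of the 13 subgroup
    representatives at the low concentration, and vehicle / positive-control
    wells.  RLU = baseline * (1 - effect) * lognormal noise; a combination's
    effect is the Bliss expectation of its components' low-dose effects plus
    any configured excess, clipped to [0, 1].

    Returns (plates, truth): ``plates`` maps cell line -> well table, ``truth``
    holds the generating single effects and per-pair expected/actual combo
    effects and excesses for every line.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(len(cfg.cell_lines) + 1)
    eff = cfg.single_effects
    if eff is None:
        eff = _draw_single_effects(cfg, np.random.default_rng(ss[0]))

    plates: dict[str, pd.DataFrame] = {}
    truth_rows = []
    n_rows, n_cols = 16, 24
    for li, line in enumerate(cfg.cell_lines):
        rng = np.random.default_rng(ss[li + 1])
        e = eff[eff["cell_line"] == line].set_index(["agent", "dose_level"])["effect"]
        wells = []  # (agent1, agent2, dose_level, control, effect)
        wells += [(None, None, "none", "vehicle", 0.0)] * cfg.n_vehicle
        wells += [(None, None, "none", "positive", cfg.positive_effect)] * cfg.n_positive
        for agent in cfg.panel["agent"]:
            for lvl in ("high", "low"):
                wells += [(agent, None, lvl, "none", float(e[(agent, lvl)]))] * cfg.n_replicates
        for a, b in cfg.combo_pairs:
            ea, eb = float(e[(a, "low")]), float(e[(b, "low")])
            excess = cfg.interaction_map.get((a, b), cfg.interaction_map.get((b, a), 0.0))
            e_null = bliss_expected(ea, eb)
            e_combo = float(np.clip(e_null + excess, 0.0, 1.0))
            wells += [(a, b, "low", "none", e_combo)] * cfg.n_replicates
            truth_rows.append({"cell_line": line, "agent1": a, "agent2": b,
                               "e1_low": ea, "e2_low": eb, "bliss_null": e_null,
                               "true_excess": e_combo - e_null, "true_combo_effect": e_combo})
        effects = np.array([w[4] for w in wells])
        rlu = cfg.baseline_rlu * (1.0 - effects) * _lognormal_noise(rng, cfg.noise_cv, len(wells))
        rlu = np.maximum(rlu, 1e-9)
        df = pd.DataFrame(wells, columns=["agent1", "agent2", "dose_level", "control", "true_effect"])
        df.insert(0, "well", [f"{chr(ord('A') + i // n_cols)}{i % n_cols + 1}" for i in range(len(df))])
        df["row"] = [w[0] for w in df["well"]]
        df["col"] = [int(w[1:]) for w in df["well"]]
        df["rlu"] = rlu
        df["cell_line"] = line
        plates[line] = df
    truth = pd.DataFrame(truth_rows)
    truth = truth.merge(eff, how="left", left_on=["cell_line", "agent1"],
                        right_on=["cell_line", "agent"]).drop(columns=["agent", "dose_level", "effect"])
    return plates, truth


# ---------------------------------------------------------------------------
# dose-response curves
# ---------------------------------------------------------------------------

def gen_dose_response(
    m: float,
    dm: float,
    doses: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 1,
    agent: str = "agent",
) -> pd.DataFrame:
    """Single-agent viability series from the median-effect model.

    Viability = (1 - fa(D)) * lognormal noise, fa(D) = (D/Dm)^m / (1+(D/Dm)^m).
    """
    if m <= 0 or dm <= 0:
        raise ValueError("m and Dm must be positive")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    rng = np.random.default_rng(seed)
    fa = median_effect_fa(doses, m, dm)
    rows = []
    for rep in range(1, n_replicates + 1):
        v = (1.0 - fa) * _lognormal_noise(rng, noise_cv, len(doses))
        for d, vi in zip(doses, v):
            rows.append({"agent": agent, "partner_agent": None, "dose": d,
                         "partner_dose": np.nan, "viability": vi, "replicate": rep})
    return pd.DataFrame(rows)


def gen_combo_dose_response(
    params_a: tuple[float, float],
    params_b: tuple[float, float],
    doses_a: Sequence[float],
    ratio: float,
    excess: float = 0.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
    n_replicates: int = 1,
    agent: str = "A",
    partner_agent: str = "B",
) -> pd.DataFrame:
    """Constant-ratio combination series with Bliss-excess ground truth.

    At each point the component doses are (d, ratio*d); the combined fraction
    affected is the Bliss expectation of the two median-effect components plus
    ``excess``, clipped to [0, 1].
    """
    doses_a = np.asarray(doses_a, dtype=float)
    if np.any(doses_a <= 0) or ratio <= 0:
        raise ValueError("doses and ratio must be positive")
    rng = np.random.default_rng(seed)
    fa_a = median_effect_fa(doses_a, *params_a)
    fa_b = median_effect_fa(ratio * doses_a, *params_b)
    fa = np.clip(bliss_expected(fa_a, fa_b) + excess, 0.0, 1.0)
    rows = []
    for rep in range(1, n_replicates + 1):
        v = (1.0 - fa) * _lognormal_noise(rng, noise_cv, len(doses_a))
        for d, vi in zip(doses_a, v):
            rows.append({"agent": agent, "partner_agent": partner_agent, "dose": d,
                         "partner_dose": ratio * d, "viability": vi, "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# xenograft growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimConfig:
    """Design of a synthetic xenograft growth study.

    Default group growth rates mirror the published cell-derived xenograft
    experiment: vehicle ~9.5%/day, Bcl-xL inhibitor ~6.5%, ADC ~3.5%,
    combination ~1.5%.
    """

    groups: Sequence[tuple[str, float]] = (
        ("vehicle", 0.095),
        ("A-1331852", 0.065),
        ("MGC018", 0.035),
        ("combination", 0.015),
    )
    n_animals_per_group: int = 7
    days: Sequence[int] = (0, 3, 7, 10, 14, 17, 21, 24, 28)
    v0_mean: float = 100.0
    animal_sd: float = 0.2
    residual_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        days = np.asarray(self.days)
        if np.any(np.diff(days) <= 0):
            raise ConfigurationError("days must be strictly increasing")
        for label, g in self.groups:
            if g <= -1:
                raise ConfigurationError(f"group {label}: daily growth fraction must exceed -1")
        if self.v0_mean <= 0 or self.animal_sd < 0 or self.residual_sd < 0:
            raise ConfigurationError("v0_mean must be positive; SDs non-negative")


def gen_growth_study(cfg: GrowthSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate longitudinal tumor volumes.

    log V_it = log v0 + a_i + log(1+g) * day_t + eps_it with a_i ~ N(0,
    animal_sd^2) and eps ~ N(0, residual_sd^2), i.e. exponential growth with a
    per-animal lognormal starting volume and lognormal measurement noise.

    Returns (volumes, truth): long-format (animal_id, group, day, volume_mm3)
    and the generating per-group slopes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    days = np.asarray(cfg.days, dtype=float)
    rows = []
    truth = []
    animal = 0
    for label, g in cfg.groups:
        slope = np.log1p(g)
        truth.append({"group": label, "daily_growth_fraction": g, "log_slope": slope,
                      "daily_growth_pct": 100.0 * g})
        for _ in range(cfg.n_animals_per_group):
            animal += 1
            a_i = rng.normal(0.0, cfg.animal_sd)
            eps = rng.normal(0.0, cfg.residual_sd, size=len(days))
            logv = np.log(cfg.v0_mean) + a_i + slope * days + eps
            for d, lv in zip(days, logv):
                rows.append({"animal_id": f"M{animal:03d}", "group": label,
                             "day": int(d), "volume_mm3": float(np.exp(lv))})
    return pd.DataFrame(rows), pd.DataFrame(truth)
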