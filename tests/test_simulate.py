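"""Generator contracts: determinism, truth-table exactness, design shapes."""

import numpy as np
import pandas as pd
import pytest

from adccombo import (
    GrowthSimConfig,
    MedianEffectModel,
    MifSimConfig,
    ScreenSimConfig,
    bliss_expected,
    gen_dose_response,
    gen_growth_study,
    gen_mif_dataset,
    gen_screen_plate,
    median_effect_fa,
    summarize_cores,
)
from adccombo.simulate import ConfigurationError


def _iid_cfg(**kw):
    """Config with no latent tumor/core effects: cells are i.i.d. per tumor."""
    return MifSimConfig(patient_effect_sd=0.0, tumor_effect_sd=0.0, core_effect_sd=0.0, **kw)


class TestMifGenerator:
    def test_fixed_seed_is_bit_identical(self, small_mif_cfg):
        a_cells, a_truth = gen_mif_dataset(small_mif_cfg)
        b_cells, b_truth = gen_mif_dataset(small_mif_cfg)
        pd.testing.assert_frame_equal(a_cells, b_cells)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_cohort_design_shape(self):
        cfg = _iid_cfg(n_patients=58, n_tumors_total=176, cores_per_tumor=3,
                       cells_per_core=5, seed=0)
        cells, truth = gen_mif_dataset(cfg)
        assert cells["core_id"].nunique() == 176 * 3
        assert cells["tumor_id"].nunique() == 176
        assert cells["patient_id"].nunique() == 58
        assert len(truth) == 176

    def test_perfect_coupling_intersects_at_marginal(self):
        # coupling +1: positivity is comonotone, so co-positive = min(marginals)
        model = {ph: {m: (0.70, 0.10, 0.10, 0.10) for m in ("b7h3", "psma", "steap1")}
                 for ph in ("AR+/NE-", "AR+/NE+", "AR-/NE-", "AR-/NE+")}
        cfg = _iid_cfg(n_patients=2, n_tumors_total=4, cells_per_core=2000,
                       marker_model=model, copositivity_coupling=1.0, seed=3)
        cells, truth = gen_mif_dataset(cfg)
        assert np.allclose(truth["true_copos_b7h3_psma"], 0.30)
        cores = summarize_cores(cells)
        # every positive cell is positive for all markers
        assert np.allclose(cores["copos_b7h3_psma"],
                           np.minimum(cores["pos_frac_b7h3"], cores["pos_frac_psma"]))
        se = np.sqrt(0.3 * 0.7 / (4 * 3 * 2000))
        assert abs(cores["copos_b7h3_psma"].mean() - 0.30) < 3 * se

    def test_zero_coupling_gives_independence_product(self):
        model = {ph: {"b7h3": (0.60, 0.2, 0.1, 0.1), "psma": (0.50, 0.2, 0.2, 0.1),
                      "steap1": (0.60, 0.2, 0.1, 0.1)}
                 for ph in ("AR+/NE-", "AR+/NE+", "AR-/NE-", "AR-/NE+")}
        cfg = _iid_cfg(n_patients=2, n_tumors_total=4, cells_per_core=3000,
                       marker_model=model, copositivity_coupling=0.0, seed=4)
        cells, truth = gen_mif_dataset(cfg)
        assert np.allclose(truth["true_copos_b7h3_psma"], 0.4 * 0.5)
        cores = summarize_cores(cells)
        se = np.sqrt(0.2 * 0.8 / (4 * 3 * 3000))
        assert abs(cores["copos_b7h3_psma"].mean() - 0.20) < 3 * se

    def test_marginals_converge_to_configured_values(self):
        cfg = _iid_cfg(n_patients=4, n_tumors_total=8, cells_per_core=2000, seed=9)
        cells, truth = gen_mif_dataset(cfg)
        cores = summarize_cores(cells)
        merged = cores.merge(truth, on="tumor_id")
        for m in ("b7h3", "psma", "steap1"):
            p = merged[f"true_pos_{m}"]
            se = np.sqrt(p * (1 - p) / 2000)
            assert (np.abs(merged[f"pos_frac_{m}"] - p) < 3.5 * se).mean() > 0.95

    def test_truth_respects_frechet_bounds(self, small_cohort):
        truth = small_cohort["truth"]
        for a, b in (("b7h3", "psma"), ("b7h3", "steap1"), ("psma", "steap1")):
            p1, p2 = truth[f"true_pos_{a}"], truth[f"true_pos_{b}"]
            co = truth[f"true_copos_{a}_{b}"]
            assert (co <= np.minimum(p1, p2) + 1e-9).all()
            assert (co >= np.maximum(0, p1 + p2 - 1) - 1e-9).all()
            assert (truth["true_triple_pos"] <= co + 1e-9).all()

    def test_invalid_probability_vector_rejected(self):
        model = {ph: {m: (0.5, 0.5, 0.5, 0.5) for m in ("b7h3", "psma", "steap1")}
                 for ph in ("AR+/NE-", "AR+/NE+", "AR-/NE-", "AR-/NE+")}
        with pytest.raises(ConfigurationError):
            MifSimConfig(marker_model=model)
        with pytest.raises(ConfigurationError):
            MifSimConfig(copositivity_coupling=-0.9)


class TestScreenGenerator:
    def test_pair_count_and_determinism(self, screen_cfg):
        assert len(screen_cfg.combo_pairs) == 78
        plates_a, truth_a = gen_screen_plate(screen_cfg)
        plates_b, truth_b = gen_screen_plate(screen_cfg)
        pd.testing.assert_frame_equal(plates_a["C4-2B"], plates_b["C4-2B"])
        pd.testing.assert_frame_equal(truth_a, truth_b)
        plate = plates_a["C4-2B"]
        assert len(plate) == 384
        n_combo_wells = plate["agent2"].notna().sum()
        assert n_combo_wells == 78 * screen_cfg.n_replicates

    def test_zero_noise_rlu_is_exact(self):
        cfg = ScreenSimConfig(seed=0, noise_cv=0.0)
        plates, _ = gen_screen_plate(cfg)
        plate = plates["C4-2B"]
        veh = plate.loc[plate["control"] == "vehicle", "rlu"]
        assert np.allclose(veh, cfg.baseline_rlu)
        treated = plate[plate["control"] == "none"]
        assert np.allclose(treated["rlu"], cfg.baseline_rlu * (1 - treated["true_effect"]))

    def test_zero_excess_pairs_sit_on_bliss_null(self):
        cfg = ScreenSimConfig(seed=1, noise_cv=0.0)
        _, truth = gen_screen_plate(cfg)
        assert np.allclose(truth["true_combo_effect"],
                           truth["e1_low"] + truth["e2_low"] - truth["e1_low"] * truth["e2_low"])
        assert np.allclose(truth["true_excess"], 0.0)

    def test_interaction_outside_combo_set_rejected(self):
        with pytest.raises(ConfigurationError):
            ScreenSimConfig(interaction_map={("exatecan", "A-1331852"): 0.2})


class TestDoseResponseGenerator:
    @pytest.mark.parametrize("m,dm,dose,expected", [
        (2.0, 2.0, 2.0, 0.5),     # D = Dm is the median-effect dose by definition
        (2.0, 2.0, 4.0, 0.8),
        (1.0, 1.0, 3.0, 0.75),
    ])
    def test_median_effect_values(self, m, dm, dose, expected):
        assert median_effect_fa(dose, m, dm) == pytest.approx(expected)

    def test_noise_free_curve_refits_exactly(self):
        df = gen_dose_response(1.7, 0.8, [0.1, 0.3, 0.8, 2.0, 5.0])
        fit = MedianEffectModel.from_dataframe(df).fit()
        assert fit.m == pytest.approx(1.7, rel=1e-12)
        assert fit.dm == pytest.approx(0.8, rel=1e-12)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(1.0, 1.0, [0.0, 1.0])


class TestGrowthGenerator:
    def test_noise_free_trajectories(self):
        cfg = GrowthSimConfig(groups=(("vehicle", 0.10), ("rx", 0.0)),
                              n_animals_per_group=2, animal_sd=0.0, residual_sd=0.0, seed=0)
        vols, truth = gen_growth_study(cfg)
        veh = vols[vols["group"] == "vehicle"].sort_values(["animal_id", "day"])
        lv = np.log(veh["volume_mm3"].to_numpy()).reshape(2, -1)
        days = np.asarray(cfg.days, dtype=float)
        assert np.allclose(np.diff(lv, axis=1), np.log(1.1) * np.diff(days))
        flat = vols[vols["group"] == "rx"]
        assert np.allclose(np.log(flat["volume_mm3"]).groupby(flat["animal_id"]).std(), 0.0)

    def test_group_mean_slope_recovers_generating_rate(self):
        # Monte-Carlo: per-animal OLS slopes average to log(1.1) within 2 SE
        cfg = GrowthSimConfig(groups=(("vehicle", 0.10),), n_animals_per_group=50,
                              animal_sd=0.3, residual_sd=0.1, seed=11)
        vols, _ = gen_growth_study(cfg)
        slopes = [np.polyfit(g["day"], np.log(g["volume_mm3"]), 1)[0]
                  for _, g in vols.groupby("animal_id")]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - np.log(1.1)) < 2 * se

    def test_nonincreasing_days_rejected(self):
        with pytest.raises(ConfigurationError):
            GrowthSimConfig(days=(0, 3, 3, 7))


def test_bliss_expected_identities():
    assert bliss_expected(0.4, 0.5) == pytest.approx(0.7)
    assert bliss_expected(0.0, 0.37) == pytest.approx(0.37)
    assert bliss_expected(1.0, 0.2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        bliss_expected(1.2, 0.1)
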