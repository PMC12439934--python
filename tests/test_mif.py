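"""H-score, (co-)positivity, classification cascade, and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adccombo import (
    classify_tumor_positive,
    compute_h_score,
    copositive_fraction,
    patient_rollup,
    positive_fraction,
    summarize_cores,
    summarize_tumors,
    triple_positive_fraction,
)
from adccombo.mif import EmptyInputError, pairwise_rank_tests
from conftest import cells_from_classes


class TestHScore:
    @pytest.mark.parametrize("classes,expected", [
        ([3, 3, 3, 3], 300.0),                    # all strong: maximum
        ([0, 0, 0], 0.0),                         # all negative
        ([1, 2, 2, 0], 125.0),                    # 25% weak + 50% moderate
    ])
    def test_worked_examples(self, classes, expected):
        cells = cells_from_classes({"b7h3": classes})
        assert compute_h_score(cells, "b7h3") == pytest.approx(expected)

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            compute_h_score(cells_from_classes({"b7h3": []}), "b7h3")

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bounds_and_positivity_identities(self, classes):
        cells = cells_from_classes({"b7h3": classes})
        h = compute_h_score(cells, "b7h3")
        pos = positive_fraction(cells, "b7h3")
        assert 0.0 <= h <= 300.0
        assert h >= 100.0 * pos - 1e-9             # every positive cell scores >= 1
        neg = np.mean(np.asarray(classes) == 0)
        assert pos == pytest.approx(1.0 - neg)     # complement identity


class TestCopositivity:
    def test_four_cell_toy(self):
        cells = cells_from_classes({"b7h3": [1, 1, 0, 0], "psma": [2, 0, 1, 0]})
        assert copositive_fraction(cells, "b7h3", "psma") == pytest.approx(0.25)

    def test_disjoint_positivity_is_zero(self):
        cells = cells_from_classes({"b7h3": [1, 1, 0, 0, 0], "psma": [0, 0, 1, 1, 0]})
        assert copositive_fraction(cells, "b7h3", "psma") == 0.0

    def test_positive_fraction_example(self):
        cells = cells_from_classes({"psma": [1, 1, 1, 0]})
        assert positive_fraction(cells, "psma") == pytest.approx(0.75)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
                    min_size=1, max_size=60))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_frechet_bounds_and_triple(self, rows):
        cells = cells_from_classes({
            "b7h3": [r[0] for r in rows],
            "psma": [r[1] for r in rows],
            "steap1": [r[2] for r in rows],
        })
        p1 = positive_fraction(cells, "b7h3")
        p2 = positive_fraction(cells, "psma")
        co = copositive_fraction(cells, "b7h3", "psma")
        assert max(0.0, p1 + p2 - 1.0) - 1e-12 <= co <= min(p1, p2) + 1e-12
        tri = triple_positive_fraction(cells)
        assert tri <= co + 1e-12


class TestTumorSummary:
    def test_single_core_identity(self, small_cohort):
        cores = small_cohort["cores"]
        one = cores[cores["tumor_id"] == cores["tumor_id"].iloc[0]].iloc[[0]]
        tum = summarize_tumors(one)
        assert tum["copos_b7h3_psma"].iloc[0] == pytest.approx(one["copos_b7h3_psma"].iloc[0])
        assert tum["h_score_psma"].iloc[0] == pytest.approx(one["h_score_psma"].iloc[0])

    def test_core_average_and_bounds(self, small_cohort):
        cores = small_cohort["cores"].copy()
        two = cores.iloc[[0, 1]].copy()
        two["tumor_id"] = "tX"
        two["copos_b7h3_psma"] = [0.10, 0.30]
        tum = summarize_tumors(two)
        assert tum["copos_b7h3_psma"].iloc[0] == pytest.approx(0.20)
        for col in [c for c in two.columns if c.startswith(("h_score_", "copos_", "pos_frac_"))]:
            v = tum[col].iloc[0]
            assert two[col].min() - 1e-12 <= v <= two[col].max() + 1e-12

    @pytest.mark.parametrize("frac,expected", [
        (0.20, True),      # inclusive boundary at the 20% cutoff
        (0.199, False),
        (1.0, True),
        (0.0, False),
    ])
    def test_double_positive_threshold(self, frac, expected):
        assert classify_tumor_positive(frac, tau=0.20) is expected


class TestPatientRollup:
    @staticmethod
    def _tumor_table(n_pos: int, n_tot: int) -> pd.DataFrame:
        # one patient per tumor; only the b7h3/steap1 pair positive flags vary
        flags = np.zeros(n_tot, dtype=bool)
        flags[:n_pos] = True
        return pd.DataFrame({
            "tumor_id": [f"t{i}" for i in range(n_tot)],
            "patient_id": [f"p{i}" for i in range(n_tot)],
            "phenotype": "AR+/NE-",
            "positive_b7h3_psma": False,
            "positive_b7h3_steap1": flags,
            "positive_psma_steap1": False,
        })

    @pytest.mark.parametrize("n_pos,n_tot,expected_pct", [
        (102, 176, 58.0),
        (94, 146, 64.4),
    ])
    def test_cohort_percentage_arithmetic(self, n_pos, n_tot, expected_pct):
        _, cohort = patient_rollup(self._tumor_table(n_pos, n_tot))
        row = cohort[cohort["pair"] == "b7h3_steap1"].iloc[0]
        assert row["n_positive_tumors"] == n_pos
        assert row["pct_positive_tumors"] == pytest.approx(expected_pct)

    def test_patient_level_percentages(self):
        # 58 patients, 46 with their (single) tumor positive -> 79.3%
        _, cohort = patient_rollup(self._tumor_table(46, 58))
        row = cohort[cohort["pair"] == "b7h3_steap1"].iloc[0]
        assert row["pct_patients_any_positive"] == pytest.approx(79.3)
        _, cohort = patient_rollup(self._tumor_table(39, 58))
        row = cohort[cohort["pair"] == "b7h3_steap1"].iloc[0]
        assert row["pct_patients_any_positive"] == pytest.approx(67.2)

    def test_zero_positive_cohort(self):
        patients, cohort = patient_rollup(self._tumor_table(0, 12))
        assert (cohort["pct_positive_tumors"] == 0).all()
        assert not patients.filter(like="any_positive").any().any()

    def test_any_all_flags_within_patient(self):
        df = self._tumor_table(1, 2)
        df["patient_id"] = "p0"     # one patient, two tumors, one positive
        patients, _ = patient_rollup(df)
        row = patients.iloc[0]
        assert row["any_positive_b7h3_steap1"] and not row["all_positive_b7h3_steap1"]


class TestRankTests:
    def test_exact_small_sample_p(self):
        # all C(4,2)=6 rank assignments: the observed split is the most extreme,
        # two-sided p = 2/6 = 1/3
        out = pairwise_rank_tests(np.array([1.0, 2.0, 3.0, 4.0]),
                                  np.array(["a", "a", "b", "b"]))
        assert out["p_raw"].iloc[0] == pytest.approx(1 / 3)

    def test_holm_step_down(self):
        # hand application: sorted p (0.01,0.03,0.04) * (3,2,1), cummax
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.03, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_identical_groups_give_p_one(self):
        out = pairwise_rank_tests(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]),
                                  np.array(["a"] * 3 + ["b"] * 3))
        assert out["p_raw"].iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_holm_monotone_and_dominates_raw(self, small_cohort):
        out = pairwise_rank_tests(small_cohort["tumors"]["h_score_psma"],
                                  small_cohort["tumors"]["phenotype"])
        assert (out["p_holm"] >= out["p_raw"] - 1e-12).all()
        order = out.sort_values("p_raw")
        assert (np.diff(order["p_holm"]) >= -1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_rank_tests(np.array([1.0, 2.0]), np.array(["a", "a"]))


def test_summarize_cores_keeps_hierarchy(small_cohort):
    cores = small_cohort["cores"]
    cells = small_cohort["cells"]
    assert len(cores) == cells["core_id"].nunique()
    assert cores["n_cells"].sum() == len(cells)
    one_core = cells[cells["core_id"] == cores["core_id"].iloc[0]]
    assert cores["h_score_b7h3"].iloc[0] == pytest.approx(compute_h_score(one_core, "b7h3"))
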