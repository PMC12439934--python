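# adccombo

Quantitative analysis toolkit for nominating antibody–drug-conjugate (ADC)
target pairs and synergistic payload combinations in metastatic
castration-resistant prostate cancer (mCRPC).

ADC monotherapy has not produced durable responses in mCRPC. Two
complementary routes to better efficacy are (i) *dual targeting* — pairing
surface antigens (B7-H3, PSMA, STEAP1) that are co-expressed by the same
tumor cells, and (ii) *payload multiplexing* — combining cytotoxic payloads
whose joint kill exceeds what their individual effects predict. Both
questions are quantitative: the first is answered from multiplexed
immunofluorescence (mIF) of tissue-microarray cohorts, the second from
viability screens and dose–response assays, with xenograft growth curves as
the in-vivo readout. `adccombo` implements that entire analysis chain as a
tested, reusable library plus CLI, and ships synthetic-data generators with
known ground truth so every stage has a parameter-recovery test.

It is intended for computational biologists and biostatisticians working on
ADC development who start from *classified tables* (per-cell staining
classes, plate maps with raw luminescence, dose–viability series,
longitudinal tumor volumes) rather than raw images or sequencing data.

## Methods at a glance

**mIF quantification.** Each segmented cell carries an ordinal staining
class per marker (0 = negative, 1 = weak, 2 = moderate, 3 = strong). Per
core, the H-score is

    H = 1·(% weak) + 2·(% moderate) + 3·(% strong)   ∈ [0, 300]

and a cell is *positive* when its class is ≥ weak. Core metrics are averaged
over a tumor's cores; a tumor is double-positive for a marker pair when its
averaged co-positive fraction is ≥ τ (default 0.20, inclusive). Patient
roll-ups count tumors and patients positive per pair; phenotype contrasts use
Wilcoxon–Mann–Whitney rank-sum tests with Holm adjustment.

**Heterogeneity.** Within a unit (patient → tumor samples, or tumor → core
samples), the heterogeneity index is the fraction of unordered sample pairs
with discordant positivity (one ≥ τ, one < τ). The pooled estimate is the
mean of per-unit indices with a 95% percentile bootstrap CI resampling whole
units.

**Screen and synergy.** Plate wells are normalized against on-plate
controls, `v = (RLU − μ_pos)/(μ_veh − μ_pos)`, `e = 1 − v`. A pair is
nominated when its agents have different mechanism-of-action subgroups and
its Bliss excess `e_combo − (e1 + e2 − e1·e2)` reaches δ (default 0.10) in at
least two cell lines. (The nomination margin δ operationalizes the
qualitative requirement of combined kill beyond independent action; it is a
configuration choice, not a published constant.) Validated pairs are scored
with the Chou–Talalay combination index from median-effect fits
`fa/(1−fa) = (D/Dm)^m`:

    CI(fa) = d1/Dx1(fa) + d2/Dx2(fa),   Dx = Dm·(fa/(1−fa))^(1/m)

with CI < 1 synergy, = 1 additivity, > 1 antagonism.

**Growth.** Log tumor volumes are fitted with a linear mixed model (fixed:
day × treatment group; random: per-animal intercept; REML). Slopes
back-transform to daily growth percentages `100·(e^b − 1)`; contrasts are
Wald tests on the slope scale.

## Worked example

Simulate a 4-line payload screen with one implanted synergistic pair
(Bliss excess 0.25 between a DNA alkylator and a Bcl-xL inhibitor), then
nominate candidates:

```python
import adccombo as ac

cfg = ac.ScreenSimConfig(seed=7, interaction_map={("duocarmycin-TM", "A-1331852"): 0.25})
plates, _ = ac.gen_screen_plate(cfg)
noms = ac.nominate_pairs(ac.combine_effects(plates), cfg.panel)
print(noms.loc[noms.nominated, ["agent1", "agent2", "n_lines_over", "summed_excess"]])
```

```
        agent1    agent2  n_lines_over  summed_excess
duocarmycin-TM A-1331852             4       0.991482
```

Exactly the implanted pair is nominated: its excess beyond Bliss
independence exceeds δ = 0.10 in all 4 cell lines, and the summed excess
(~0.99 ≈ 4 × 0.25) ranks it first. Next, fit the xenograft growth model on a
simulated four-arm study:

```python
vols, _ = ac.gen_growth_study(ac.GrowthSimConfig(seed=3))
rates, contrasts = ac.TumorGrowthModel.from_dataframe(vols).fit().report()
print(rates); print(contrasts)
```

```
      group  daily_growth  daily_growth_pct
    vehicle 9-10% per day          9.351492
  A-1331852  6-7% per day          6.458465
     MGC018    4% per day          3.777778
combination  1-2% per day          1.446218

                contrast daily_rate_change       p_value
    vehicle vs A-1331852              2-3%  2.496166e-46
       vehicle vs MGC018              5-6% 4.201888e-171
  vehicle vs combination                8%  0.000000e+00
     A-1331852 vs MGC018              2-3%  4.412011e-42
A-1331852 vs combination                5% 1.051416e-145
   MGC018 vs combination              2-3%  9.212809e-34
```

Vehicle tumors grow 9–10% per day; the ADC/Bcl-xL-inhibitor combination
suppresses growth to 1–2% per day, and adding the Bcl-xL inhibitor to the
ADC removes a further 2–3 percentage points of daily growth (p < 0.001) —
the ranges are 95% CI bounds rounded to whole points.

The full pipeline (mIF cohort → classification → heterogeneity → screen →
combination index → growth) runs from one seed:

```bash
adccombo run --outdir myrun --seed 11     # writes ~20 CSVs + manifest.json
```

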