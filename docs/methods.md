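# Methods

This note documents the statistical models implemented in `adccombo`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the underlying analysis convention was genuinely open.

## 1. mIF quantification

### Model

The atom is a segmented cell with an ordinal staining-intensity class per
marker, `0 = negative, 1 = weak, 2 = moderate, 3 = strong`, for B7-H3, PSMA
and STEAP1. All downstream quantities are deterministic aggregations:

* **H-score** over a set of cells: `H = Σ_k k · pct(class = k)` with
  percentages on the 0–100 scale, so `H ∈ [0, 300]`. Equivalently
  `H = 100 · mean(class)`, which is how it is computed.
* **Positivity**: class ≥ weak. Pooling weak/moderate/strong is the standard
  percent-positive convention for this assay and makes
  `positive_fraction = 1 − fraction(negative)` an identity used in tests.
* **Co-positivity** of a pair (or all three markers): the fraction of cells
  positive for every marker involved. It is bounded by the Fréchet limits
  `[max(0, p1+p2−1), min(p1, p2)]`; the property suite checks this on random
  and generated cores.
* **Cascade**: core metrics → unweighted mean over a tumor's cores → tumor
  double-positive call at threshold τ applied to the *core-averaged*
  co-positive fraction (inclusive ≥) → patient counts (any / all tumors
  positive). τ defaults to 0.20, the cohort-analysis cutoff this package is
  built around. Applying τ to the tumor-level average while retaining
  per-core fractions reconciles tumor classification with intra-tumoral
  heterogeneity, which needs the per-core values.

Reported percentages are rounded to one decimal; internal computation is
full precision.

### Phenotype contrasts

Tumor-level averaged H-scores are compared across the four mCRPC phenotypes
(AR+/NE−, AR+/NE+, AR−/NE−, AR−/NE+) with two-sided
Wilcoxon–Mann–Whitney tests: exact enumeration when the combined sample is
≤ 10 without ties, otherwise the normal approximation with midrank tie
correction (`scipy.stats.mannwhitneyu`). Multiplicity is handled by Holm's
step-down method (`statsmodels`). The switch point at n = 10 is a numerical
choice; the exact and asymptotic p-values agree closely in that range.

## 2. Heterogeneity indices

A *unit* is a patient (samples = tumor-level co-positive fractions of its
metastatic sites) or a tumor (samples = core-level fractions). A sample pair
is discordant when exactly one member is ≥ τ. The unit index is the fraction
of its `n(n−1)/2` unordered pairs that are discordant — in closed form
`2k(n−k)/(n(n−1))` with `k` positives — and it is checked against exhaustive
pair enumeration in the tests. Units with fewer than two samples carry no
pairs and are excluded as non-informative.

The pooled point estimate is the arithmetic mean of per-unit indices
(equal unit weights; a pair-weighted pool is available via
`weighting="pair"`). There is no single established convention for pooling
clustered discordance indices; the arithmetic mean of unit indices was
adopted as the transparent choice and is documented as such. Absolute values
are therefore comparable only between analyses using the same pooling rule.

The 95% CI is a percentile bootstrap with B = 2000 replicates resampling
*whole units* with replacement, which respects the clustering of samples
within patients/tumors. The bootstrap is seeded and deterministic. When a
resample is degenerate the percentile interval is widened minimally to
bracket the point estimate. The index is invariant to sample order and to
any monotone transform of the fractions that preserves the side of τ
(property-tested).

## 3. Payload screen and synergy nomination

### Normalization

Each 384-well plate carries ≥ 3 vehicle and ≥ 3 positive-control
(staurosporine) wells. Relative viability is anchored to the control means,
`v = (RLU − μ_pos)/(μ_veh − μ_pos)`, clipped to [0, 1]; fraction affected is
`e = 1 − v`. Replicate wells are averaged after normalization. Screen
normalizations vary between labs; the control-anchored formula — the
standard choice for ATP-luminescence screens — is used here and `log10(RLU)`
is emitted alongside for reporting. Normalization is invariant to rescaling all RLU by a constant
(tested).

### Nomination

The screen criterion — combined toxicity beyond what the agents' independent
effects predict — is operationalized as a **Bliss excess**:
`excess = e_combo − (e1 + e2 − e1·e2)` computed per cell line from low-dose
effects. A pair is nominated when

1. its agents belong to different pharmacological subgroups (distinct
   mechanism of action), and
2. `excess ≥ δ` in at least `min_lines` cell lines (defaults δ = 0.10,
   `min_lines = 2`).

δ is a configuration parameter of this package, not a community constant. Candidates are
ranked by the excess summed over qualifying lines. On null screens
(no implanted interaction) the nomination list is empty across 100 seeds at
δ = 0.10 (tested); the margin is what buys that specificity at the default
noise level (CV 5%, 3 replicate wells).

### Median-effect fits and combination index

Dose–response series are fitted with the median-effect model
`fa/(1−fa) = (D/Dm)^m` by least squares on
`log10(fa/(1−fa)) vs log10(D)`; `m` is the slope, `Dm = 10^(−intercept/m)`,
and `r` is the correlation coefficient of the linearized fit. Fractions
affected are clipped to `[ε, 1−ε]` with ε = 0.005 — points at 0 or 1 carry
no information on the logit scale — and raw points outside (0, 1) are
dropped. Fits with `m ≤ 0` are flagged non-cytotoxic rather than rejected.
Noise-free model data is inverted to machine precision (tested over a
3 × 3 parameter grid).

For a constant-ratio combination, the combination index at effect level fa
is the mutually-exclusive (Loewe-form) expression
`CI = d1/Dx1(fa) + d2/Dx2(fa)`; the non-exclusive form adding
`d1·d2/(Dx1·Dx2)` is available behind `form="nonexclusive"`. Two summaries
are reported: **CI at ED50** (fa = 0.5), obtained by refitting the
median-effect model to the combination on total dose and splitting by the
fixed component ratio, and the **mean CI** over the achieved-fa grid. Single-number CI
summaries in the literature rarely state the effect level they were read at,
so ED50 is the default summary here. Classification uses
CI < 1 for synergy with a reporting band of 1 ± 0.05 labelled "additive" so
that near-exact additivity is not over-called. The strongest end-to-end
oracle is the sham combination — a drug paired with itself at split doses —
which must give CI = 1 at every fa; the tests require agreement to 1e−9.
Note that a Bliss-mixture combination curve is not exactly median-effect
shaped, so the ED50 summary is a (good) approximation where the per-point
CIs are exact; the tests therefore compare per-point CIs against a dense
grid-inversion oracle and check the ED50 value by sign.

## 4. Growth model

Longitudinal volumes are modeled on the natural-log scale:

    log V_it = β0 + u_i + β_g(i) · day_t + γ_g(i) + ε_it,
    u_i ~ N(0, σ_a²),  ε_it ~ N(0, σ²)

i.e. fixed effects for day, group and their interaction, random intercept
per animal, estimated by REML (`statsmodels MixedLM`). The log base is
irrelevant after back-transform but is natural-log throughout. Day is
numeric (linear). Per-group slopes convert to daily growth percentages
`100·(e^β − 1)`; group contrasts are formed on the slope scale and
translated to percentage-point-per-day differences anchored at the
comparator's fitted slope.

Inference is Wald (normal) on the REML fit. Satterthwaite or Kenward–Roger
degree-of-freedom corrections are not provided by the mixed-model backend;
at the design sizes this package targets (≥ 6 animals/group, ≥ 7
timepoints) the simulation suite shows 95% CI coverage of generating slopes
within 92–98% over 500 seeded replicates, so the normal reference is
retained and documented rather than approximated ad hoc.

Degenerate noise-free designs make the REML likelihood singular; the model
detects a ~zero residual scale and falls back to exact least squares with
animal fixed effects, recovering generating slopes exactly with zero-width
intervals (this is also what makes the "noise-free 10%/day → exactly 10.0"
contract testable).

The growth report formats each group's rate as the 95% CI bounds rounded to
whole percentage points ("9–10% per day"); ranges in that style are always
interval bounds here, and are labelled as such, since bare rate ranges are
otherwise ambiguous.

## 5. Synthetic-data generators

All generators draw from one integer seed through `numpy` SeedSequence
spawning; fixed seed ⇒ bit-identical tables (tested). Each returns the
generating truth alongside the data.

### mIF cohort

Default design: 58 patients, 176 tumors total (allocated near-evenly, each
patient ≥ 1), 3 cores/tumor, 200 cells/core — the synthetic analogue of a
rapid-autopsy TMA cohort. Tumor phenotypes are drawn with the cohort mix
(AR+/NE− 146/176; the remainder split across the other three phenotypes).

Per-cell classes arise from a **Gaussian copula**: a latent standard-normal
vector per cell with equicorrelation ρ (`copositivity_coupling`,
default 0.5) across the three markers, cut at the per-phenotype class
quantiles. ρ = 0 gives independent markers (co-positivity = product of
marginals), ρ = 1 comonotone markers (co-positivity = min of marginals), so
the coupling sweeps the full Fréchet range; for three markers the
equicorrelation matrix is positive semi-definite only for ρ ≥ −0.5, and the
config rejects values below that.

Latent Gaussian shifts shared at the patient (SD 0.40), tumor (SD 0.30) and
core (SD 0.15) levels create the between-patient, between-tumor and
between-core variation in staining fractions that real cohorts show; they
are what make tumor classification non-trivial and heterogeneity indices
non-zero. The truth table is computed *conditionally on the realized
shifts* — per core, marginal positivity is a normal tail probability and
joint positivity a (seeded, deterministic) multivariate-normal orthant
probability; per-tumor truth is the mean over its cores — so recovery tests
compare against exact generating fractions, not approximations.

The per-phenotype class frequencies are free parameters, not calibrated
claims. The defaults were chosen once so the cohort sits in the regime of a
real mCRPC TMA: roughly one third of AR-active cells double-positive per
pair, a middling majority of tumors crossing the 20% threshold, intra-tumoral
discordance ~0.1 and intra-patient discordance ~0.3.

What the generator does **not** emulate: spatial structure within cores,
cell segmentation or classification error, variable cells-per-core, missing
cores, or any dependence of staining on clinical covariates. Passing
recovery tests therefore show the *estimators* are correct under clustered
sampling, not that the pipeline is robust to imaging artifacts.

### Screen plates

One 384-well plate per cell line: 23 agents at high and low working
concentrations, all 78 pairwise combinations of the 13 subgroup
representatives at low concentration, 3 replicate wells each, plus 6 vehicle
and 6 positive-control wells (16 × 24 layout, filled row-major). Default
single-agent effects are drawn per line (low dose U(0.05, 0.6); high dose
scaled up, capped at 0.95); a combination's effect is the Bliss expectation
of its components plus any configured excess, clipped to [0, 1]. RLU =
`baseline · (1 − effect) · LN(cv)` with unit-mean lognormal noise
(CV default 5%) — luminescence is positive-valued with roughly constant CV,
which motivates multiplicative noise. The agent panel (23 payloads, 13
pharmacological subgroups, classes DDD/MDD/ID) mirrors the standard ADC
payload classes: DNA-damaging agents (topoisomerase I/II poisons, a
double-strand scissor, a crosslinker, an alkylator), microtubule disruptors
(auristatins, maytansinoids, eribulin, tubulysin) and innovative payloads
(splicing, RNA-Pol II, NAMPT, Bcl-xL inhibitors).

Not emulated: edge effects, plate drift, dispensing errors, dose–response
curvature within the two working concentrations.

### Dose–response and combinations

Single-agent curves come from the median-effect model itself (so fitting is
exact inversion in the noise-free case); constant-ratio combination curves
are Bliss mixtures of two median-effect components plus an optional constant
excess, clipped to [0, 1]. Viability carries the same multiplicative
lognormal noise.

### Xenograft growth

`log V = log v0 + a_i + log(1+g)·day + ε` with per-animal intercepts
(lognormal starting volumes around 100 mm³, the enrollment threshold) and
lognormal residuals. Default arms mirror the in-vivo experiment: vehicle
9.5%/day, Bcl-xL inhibitor 6.5%, ADC 3.5%, combination 1.5%; 7 animals per
arm; measurements twice weekly for 4 weeks. Not emulated: treatment-phase
vs off-treatment slope changes, attrition, caliper error structure, body
weight.

## 6. Default parameters

| Parameter | Default | Meaning | Status |
|---|---|---|---|
| τ | 0.20 | double-positive threshold on co-positive fraction | field convention |
| δ | 0.10 | Bliss-excess margin per line for nomination | analysis choice |
| min_lines | 2 | lines required over δ | field convention |
| CI cutoff | 1.0 | synergy boundary for the combination index | field convention |
| additive band | ±0.05 | CI range reported "additive" | analysis choice |
| ε | 0.005 | fa clipping for logit fits | analysis choice |
| B | 2000 | bootstrap replicates | analysis choice |

## 7. Problem sizes used in the automated checks

The test and acceptance runs use cohort/replicate sizes chosen to make the
statistical checks sharp while keeping a full run inside a few minutes on a
single CPU: the default 58-patient/176-tumor cohort at 200 cells/core for
cohort-level checks, 50–100 seeded screens for nomination specificity, 100
seeds for noisy median-effect recovery, and 200–500 seeded replicates
(8 animals/arm, 9 timepoints) for growth-model CI coverage. These sizes are
the package's own reporting choices and are stated in the relevant tests and
in `scripts/acceptance.py`.

## 8. Known limitations

* The heterogeneity estimator is the package's documented choice in the
  absence of a standard pooling convention (see §2); absolute index values
  are not comparable across different estimator choices.
* The ED50 combination-index summary inherits median-effect model error when
  the combination curve deviates from median-effect shape (§3).
* Mixed-model inference is Wald/normal; for very small designs (< 4
  animals/group) coverage will degrade and no small-sample correction is
  applied (§4).
* Generators produce idealized data (no spatial, batch, or plate artifacts);
  conclusions about robustness to such artifacts are out of scope.
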