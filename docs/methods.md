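# Methods

## Model and procedure

`snpmeta` treats each case-control study of a biallelic SNP (risk allele
G, reference allele T) as contributing a 2×2 table under a chosen genetic
contrast, and pools the resulting log odds ratios across studies.

**Per-study effect.** For a table with case exposed/unexposed counts
`a`/`b` and control counts `c`/`d`, the effect is `log(ad/bc)` with the
Woolf large-sample standard error `sqrt(1/a + 1/b + 1/c + 1/d)`; 95%
confidence bounds are `exp(logOR ± z·SE)` with `z` the exact 97.5% normal
quantile (1.959964…), not a hard-coded 1.96 — both agree with 3-decimal
reporting. When any cell is zero, 0.5 is added to all four cells (Haldane
correction) and the table is flagged `corrected`; the study is retained,
never dropped. The alternative policy `none` refuses such tables. The
correction is applied at estimation time and never stored in the counts.

**Fixed effects.** Inverse-variance weighting: `w_i = 1/SE_i²`, pooled
log OR `Σw_i y_i / Σw_i`, pooled SE `1/sqrt(Σw_i)`. A Mantel–Haenszel
alternative (`pool_fixed_mh`) pools the raw tables as
`Σ(a_i d_i/n_i) / Σ(b_i c_i/n_i)` with the Robins–Breslow–Greenland
variance; several widely used meta-analysis programs default to MH, and on
the bundled data the two routes agree to three decimals (the bundled
Asian-descent subgroup rounds to 1.130 under MH and 1.129 under IV — the
published value matches the MH rounding).

**Heterogeneity.** Cochran's `Q = Σ w_i (y_i − ŷ_fixed)²` referred to
χ² with df = k−1 (k = 1 returns Q = 0, df = 0, P = 1 by convention);
`I² = max(0, (Q−df)/Q)·100`, reported as a percentage with two decimals;
DerSimonian–Laird `τ² = max(0, (Q−df)/(Σw − Σw²/Σw))`. Both I² and τ²
are floored at zero. Heterogeneity is called at P < 0.10, the
conventional threshold for this test's low power at small k.

**Random effects.** DL weights `1/(SE_i² + τ²)`; when τ² = 0 the result
equals the fixed-effect result exactly (verified bit-for-bit in tests).
No Hartung–Knapp adjustment and no REML/Paule–Mandel τ² are offered.

**Model selection.** Fixed effects when I² < 50%, random effects
otherwise; the threshold is strict (I² exactly 50 selects random). The
threshold is configurable (`AnalysisConfig.i2_threshold`).

**Hardy-Weinberg QC.** Controls of each genotype-resolution study are
tested against HW proportions `p², 2pq, q²` at the estimated G frequency
`p = (2·GG + GT)/2N` by a Pearson 1-df chi-square without continuity
correction — the convention of the genetic-association meta-analysis
literature. An exact conditional mid-P test is available for small
samples (`hwe_exact_midp`). The filter default is α = 0.05; deviating
studies are removed and the whole grid re-computed. Monomorphic controls
fit HW exactly and are flagged, not refused. Allele-resolution records
carry no genotype information and pass through as not-testable.

**Publication bias.** Egger's classical (1997) regression: unweighted OLS
of the standard normal deviate `y_i/SE_i` on precision `1/SE_i`; the
intercept's t statistic has k−2 df, two-sided P. A weighted
(inverse-variance WLS) variant is available. At least three studies are
required. Funnel data (study, log OR, SE) export for external plotting;
no images are rendered.

**Sensitivity.** Leave-one-out: the pool is re-run k times, omitting each
study in turn, with the same model-selection rule.

**Power.** Two-sided normal approximation to the Wald test of log OR = 0:
with noncentrality `|log OR|/SE` and critical value `z_{1−α/2}`, power =
`Φ(ncp − z) + Φ(−ncp − z)`. It equals α at OR = 1 and is symmetric in
OR ↔ 1/OR. Results carry a `method_note` flagging the approximation;
power figures printed by proprietary packages rest on unstated
assumptions and are not comparison targets.

**Workflow.** `run_full_analysis` computes the (subgroup ∪ "All") ×
contrast grid, repeats it after HWE filtering, and attaches leave-one-out
and Egger results per contrast. Subgroups are data-driven labels from the
input's `subgroup` column — nothing is hard-coded. Cells a table cannot
support (genotype contrasts on allele-resolution records) are reported as
not-computable and the run continues. `run_stratified_analysis` reuses the
identical engine on case-case tables for invasiveness strata — aggressive
(Gleason score ≥ 7, PSA > 10 ng/mL, or metastatic / clinical stage ≥ T3)
versus non-aggressive cases — since such a table is structurally a 2×2
grid like any other. Every HWE exclusion, continuity correction and
model-selection decision is logged at info level.

## Input schema

Delimited text (tab or comma, auto-detected; tab on write) with metadata
columns `study_id, year, country, subgroup` and either genotype columns
`case_GG, case_GT, case_TT, ctrl_GG, ctrl_GT, ctrl_TT` or allele columns
`case_G, case_T, ctrl_G, ctrl_T`. Counts are strict non-negative
integers; fractional values are rejected. Optional `n_case`/`n_control`
columns are cross-checked against the counts; mismatches warn rather than
fail, because published tables occasionally disagree with their own
printed totals. Both resolutions are supported because published
combined tables often print only allele counts while the genotype-model
contrasts need genotype splits; the package refuses to guess a genotype
split from allele counts.

## Synthetic-data generator

`SimulationDesign` draws control genotypes from HW proportions at
frequency `p_g`, distorted (when requested) by an inbreeding coefficient
F: `(p²+Fpq, 2pq(1−F), q²+Fpq)` — F moves mass from heterozygotes to
homozygotes without changing the allele frequency, which is exactly the
deviation the HWE filter should catch. Case genotypes use the
retrospective tilting model: control probabilities reweighted by genotype
odds ratios (`or_het` for GT vs TT, `or_hom` for GG vs TT) and
renormalized — the standard construction for case-control SNP simulation
and the data-generating process the OR contrasts assume. Between-study
heterogeneity is one study-level effect δ ~ N(0, τ²) multiplying both
odds ratios on the log scale, matching the single-τ² DL model fitted
downstream. Under the multiplicative dose model (`or_hom = or_het²`, via
`SimulationDesign.from_allele_or`) both arms are in HW proportions and
the population per-allele OR equals `or_het` exactly, which gives the
estimand for bias and coverage checks.

Defaults: 7 studies, 200 cases and 200 controls per study, `p_g = 0.33`
(the pooled control G-allele frequency of the bundled published studies),
null odds ratios, τ = 0, F = 0. These are the conditions under which the
engine's calibration is checked: with 2000 replicates, Cochran's Q
rejects at P < 0.10 in 10% ± 2% of null tables and the pooled 95% CI
covers OR = 1 in 95% ± 2%; with k = 20 studies of 2000/arm at per-allele
OR 1.3, 500 replicates bound the pooled log-OR bias below 0.02; control
arms simulated with F = 0.3 at n = 500 are flagged by the HWE filter in
over 90% of replicates while F = 0 arms are flagged at the nominal 5%.
These replicate counts keep each Monte-Carlo check's standard error a few
times smaller than the band it must land in while the whole suite runs in
seconds.

What the generator does **not** emulate: genotyping error, population
stratification or admixture within a study, covariate confounding,
selective reporting within studies, or correlated effects across strata
of one study. Passing calibration therefore shows the estimator and its
QC behave correctly under the assumed sampling model, not that real
published collections satisfy that model.

## Numerical choices and edge cases

- All pooling is done on the log-OR scale; exponentiation only for
  reporting. Output tables round to 3 decimals (ORs, CIs, P) and 2
  decimals for I², matching the field's reporting style.
- Single-study pools short-circuit to the study's own estimate exactly
  (no floating round-trip through weights).
- `I²` uses `max(0, ·)`; `Q ≤ df` therefore forces τ² = 0 and makes
  random- and fixed-effects results identical.
- Monomorphic tables: the HWE test returns χ² = 0, P = 1 with a flag;
  odds-ratio estimation on a table whose both diagonals vanish raises a
  degenerate-table error.
- Ties in the exact mid-P enumeration contribute half their probability.
- Egger's regression with identical effects *and* identical standard
  errors is a degenerate design and raises.
- Reproducibility: one integer seed drives the generator through
  `numpy.random.default_rng`; a fixed design + seed yields a bit-identical
  table, and re-running an analysis on the same input is deterministic.

## Design choices made where the design was open

- **Fixed-effects default: inverse variance.** Transparent weights, exact
  agreement with the DL limit at τ² = 0, and three-decimal agreement with
  MH on the bundled data; MH is one flag away for sparse tables.
- **HWE test: chi-square, not exact, by default.** The chi-square form is
  what the association-study QC literature and most published
  meta-analyses use; the exact mid-P variant is provided for small
  samples rather than silently switching by sample size.
- **Continuity correction only on demand** (a zero cell), never
  unconditionally, so well-populated tables are untouched and the
  correction is visible in the output flag.
- **Subgroups as data labels.** Ethnicity strata are values of one input
  column; the engine never special-cases a particular grouping, which is
  also what lets the invasiveness-stratified (case-case) analysis reuse
  the machinery unchanged.
- **Egger variant: classical unweighted OLS** as the default because it
  is the form the name usually refers to; the weighted variant exists but
  changes the test, so it is opt-in.

## Known limitations

- Wald CIs and the chi-square Q are large-sample approximations; with
  very small studies or rare alleles, exact or score-based intervals
  would behave better and are not provided.
- τ² is the DL moment estimator only; REML or Paule–Mandel alternatives
  (and Hartung–Knapp CIs) are out of scope.
- Genotype-model contrasts cannot be computed from allele-only input, so
  combined tables printing only allele counts support only the
  per-allele analysis.
- The power calculation is an approximation for planning intuition, not a
  reproduction of any specific power software.
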