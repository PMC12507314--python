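# Methods

This note documents the statistical and numerical choices behind `bcqci`:
what the model computes, which parameters matter, what the synthetic cohort
does and does not emulate, and where the design was genuinely open.

## The BC-QCI model

Each patient's care episode is anchored at the **QCI date** (start of the
first specialized-burn-care episode); outcomes and costs are measured over
the following **QCI period** (default 12 months, `AnalysisConfig.followup_months`).
When a patient has several episodes only the first is analysed. Textbook
outcome (TO) is the unweighted conjunction of the five indicators — there is
deliberately no partial credit or weighting — and the QCI value is

    QCI = (TO proportion × 100) / (average total cost / 1000 €),

a dimensionless "outcome points per thousand euros". It is homogeneous of
degree −1 in cost and linear in the TO proportion; both properties are
tested. Quarters are formed on the QCI date (not discharge), so a patient
admitted in March and discharged in May counts in Q1.

## Risk models and their provenance

Two external prediction models enter the thresholds. Neither is re-estimated
from data; both are configuration (`RiskModelConfig`), and every report's
metadata records the coefficients used.

* **Mortality.** Revised Baux score `B = age + %TBSA + 17·[inhalation]`,
  mapped to risk by `expit(β₀ + β₁B)`. The shipped defaults
  (β₀ = −8.33, β₁ = 0.076) place 50% predicted mortality at B ≈ 109.6,
  consistent with modern burn-center survival; centers with a locally fitted
  logistic should substitute their own values. The failure cutoff is a
  predicted risk ≤ 0.25: a death below it counts as unexpected.
* **Length of stay.** A linear predictor on age (0.045 d/yr), %TBSA
  (1.15 d/%) and inhalation injury (4 d), intercept 0.3 d, clamped at zero.
  This encodes the classic "about one hospital day per %TBSA" rule plus age
  and inhalation terms. The functional form of published LOS models is richer
  (interactions, nonlinearity); the linear form is an explicit approximation
  and the coefficients are replaceable. Predicted LOS is kept continuous —
  rounding it before the `actual > predicted` comparison would silently relax
  the threshold.

**Boundary semantics** follow a literal reading of the threshold set: LOS
fails only on *strictly greater*, the mortality cutoff is *inclusive* (≤),
TBSA band edges are right-closed (5% is in 0–5, 20% is in 11–20), and age 60
belongs to the 18–60 band. The mortality rule's attribution clause is read
conjunctively (fail = died **and** attributed **and** low predicted risk);
the grammatically possible disjunctive reading is available as
`AnalysisConfig.mortality_rule = "any_attributed_or_low_risk"` rather than
being silently chosen. Deceased patients fail the discharge-destination
indicator (one cannot be discharged home), which keeps TO a subset of
survivors.

## Micro-costing

Per-patient cost = Σ item volume × unit price, grouped into burn-center
stay, treatment, clinical consultation and outpatient burn care. Only the
ICU-day (€3894) and non-ICU-day (€1245) prices are published figures; the
other fifteen items in `data/unit_prices_2023.csv` are replaceable
placeholders chosen so the default synthetic cohort's category averages land
near the published cost table. Prices carry a price year; chained annual
inflation factors update them to the analysis year (identity when the years
match; a missing index year is a configuration error, never silently 1.0).

Readmission days are costed on the patient who incurred them at the non-ICU
rate; because group reporting divides pooled category totals by the full
cohort size, their cost is automatically spread over all patients, and the
average of per-patient totals equals the category-pooled average exactly.
All arithmetic is in full float precision; euro rounding is presentation
only — category totals are the canonical consistency check
(`total = Σ categories` to the cent), since independently rounded sub-items
need not add up to a rounded total.

Confidence intervals for mean costs use the **percentile bootstrap**
(B = 1000, seed-deterministic): the simplest defensible method for
right-skewed cost data, recorded in the report metadata. Its finite-sample
coverage for skewed data runs slightly under nominal (the test suite's
Monte-Carlo study at n = 200 with lognormal σ = 0.5 measures ~94.6% at
nominal 95%); BCa would narrow that gap at the price of a less transparent
procedure. Group comparisons use Kruskal–Wallis with tie correction and the
χ² approximation (k−1 df); an exact enumeration variant exists for n ≤ 10
and doubles as the test oracle. All observations identical is treated as
(H = 0, p = 1).

## Outcome-category costs and the minimum cell size

Comparing achieved vs failed costs per indicator requires both arms to be
interpretable: any indicator from the merge set (complications, wound
infection, predicted mortality) with fewer than `min_cell = 5` patients in
either arm is pooled into an `other` category, whose failed arm is "failed
at least one merged indicator". The merge is reported, never silent.

## Case-mix standardization

The case-mix grid is age {18–60, >60} × TBSA {0–5, 6–10, 11–20, >20} ×
etiology {flame, other} (16 cells). How to "adjust" was an open design
point; `bcqci` uses **direct standardization**: each quarter's
stratum-specific TO proportions and mean costs are re-weighted to the
whole-cohort stratum distribution. Cells absent from a quarter are dropped
with weight renormalization and logged. Crude values are always reported
alongside adjusted ones, and a quarter whose own mix equals the reference
reproduces its crude values exactly (tested).

## Synthetic cohort generator

The registries behind the model are not publicly deposited, so all testing
runs on synthetic cohorts. The generator's defaults *are* the study
conditions: n = 1449 adults over a 14-quarter window (2020-Q1 … 2023-Q2),
64% male, median age 48 (IQR 31–63, 71%/29% around age 60), median TBSA 4%
(band shares 64/16/12/8), 46% flame, 4% inhalation injury, 17% ICU, 71%
operated, 14% complications, 2% wound infection, 2% mortality, indicator
pass rates {LOS 62%, infection 98%, complications 89%, discharge 94%,
mortality 99%} and an average total cost near €29.3k.

Mechanics:

* **Marginals.** Age and TBSA come from piecewise-linear inverse CDFs
  through the quantile targets (rounded to integers); binary traits are
  Bernoulli. TBSA's distribution family is a fitting choice — any
  right-skewed family reproducing the quantile targets would do.
* **Dependence.** A single latent severity score
  `s = standardize(0.05·age + 0.12·TBSA + 1.2·inhalation) + N(0, 0.6²)`
  drives every outcome through a logistic link `expit(α + κ·slope·s)`. For
  each outcome, α is solved numerically (Brent) on the *realized* covariates
  so the configured marginal is hit in expectation regardless of κ. One
  latent factor is the minimal mechanism that makes the joint TO rate (~54%)
  exceed the independence product of the marginals (~50%); κ (default 0.85)
  was calibrated once to that joint rate. At κ = 0 all outcomes are
  independent coins, which the parameter-recovery test exploits.
* **Consistency by construction.** Actual LOS is generated *from* the LOS
  verdict (pass: `floor(pred·u^1.2)`, overrun: `floor(pred)+1+Poisson`), so
  the latent flag and the evaluated indicator agree; ICU days are clipped
  into the index admission; deceased patients are discharged "deceased" and
  consume no aftercare; the inclusion rule (≥1 admission day and/or surgery)
  is enforced. Non-home discharge is drawn among survivors only, because the
  deceased already fail the indicator — solving its marginal over everyone
  would double-count the overlap.
* **Complications.** The counted (indicator-failing) complication rate is
  controlled directly (10.8%); ARDS/polyneuropathy codes are added to
  high-TBSA patients at a rate chosen so the *recorded* complication
  marginal lands near 14% while the exemption removes them from the verdict.
* **Utilization.** Volumes are Poisson/Bernoulli with rates tied to LOS,
  surgery count and TBSA; the rate constants were calibrated once so that,
  under the shipped prices, category averages, the overall mean (~€29.3k
  in expectation) and the achieved/failed cost split (~€10k vs ~€55k)
  resemble the published structure, then frozen.

What the generator does **not** emulate: clinical trajectories, comorbidity,
center effects, seasonal or pandemic-era admission patterns (dates are
uniform), within-year cost inflation, and any joint structure beyond the one
latent factor. Passing tests therefore demonstrate that the *pipeline*
reproduces the model's arithmetic and distributional behavior on data with
realistic marginals and dependence — not that it has been validated against
the real registries.

`calibration_report()` tabulates every observed marginal against its target
with a tolerance of three binomial standard errors plus a small
model-approximation slack (wider for medians and the cost average); it is
both a CLI verb and part of the acceptance suite.

## Numerical and edge-case choices

* Seeds: one integer seed fully determines a cohort (identical config ⇒
  byte-identical records) and one analysis seed drives all bootstrap
  resampling; per-category CIs use child seeds drawn from a generator seeded
  with it.
* Empty cohorts, empty bootstrap samples, non-positive average costs,
  missing inflation years, unpriced items and unknown codes raise
  immediately with the offending name — never a silent default.
* Quarters with zero patients appear in the quarterly table with n = 0 and
  NaN values rather than being dropped, so time series keep their spacing.
* Loader: missing indicator-relevant fields exclude a patient (logged with
  the reason); the complications cell must be an explicit code list or the
  literal `none`, so an empty cell is distinguishable as "not recorded".
  Patients admitted within 12 months of the window end are kept by default
  but flagged; `include_incomplete_followup=False` excludes them instead —
  the handling of such patients was not specified and is therefore explicit
  configuration.
* Problem sizes in the test suite (cohorts of 400–10,000; 1000 bootstrap
  replicates; 1000-cohort coverage study; 2000-replicate type-I study) were
  chosen so each statistical check has enough resolution for its stated
  tolerance band while the whole suite runs in well under a minute.

## Known limitations

* The shipped risk-model coefficients are defensible defaults, not the
  fitted values of the cited publications; conclusions sensitive to them
  require locally validated coefficients.
* Fifteen of seventeen unit prices are calibrated placeholders.
* Direct standardization with renormalized weights is biased when a
  quarter's missing cells are systematically unusual; with ~100 patients per
  quarter spread over 16 cells, empty cells are common and the adjusted
  series should be read alongside the crude one.
* The percentile bootstrap undercovers slightly for heavy-tailed costs; for
  small subgroups the reported CIs are approximate.
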