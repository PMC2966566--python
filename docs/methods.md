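# Methods

This note documents the models, conventions and numerical choices behind
`sepscore`, in the order data flows through the package.

## Patient model and the normal-imputation convention

Scores are computed from *first-recorded* ED values only; the data model
is deliberately cross-sectional (no longitudinal vitals). Chart
abstraction leaves gaps, and the convention under which these scores were
originally derived treats any unrecorded variable as *normal or not
present*. `resolve()` operationalizes that convention as a total
function: every missing numeric field takes a normal sentinel, every
unrecorded history flag becomes "no", and every substitution is flagged
in a per-field provenance map (`observed` / `imputed_normal` /
`derived`).

The sentinels are chosen so that an imputed field contributes **0 points
to every score** — that is the operational meaning of "abstracted as
normal", and it is enforced by a dedicated test:

| field | sentinel | field | sentinel |
|---|---|---|---|
| age | 40 y | WBC | 8 ·10³/µL |
| heart rate | 80 /min | bands | 0 % |
| respiratory rate | 16 /min | platelets | 250 ·10³/mm³ |
| SBP / DBP | 120 / 70 mmHg | BUN | 5 mmol/L |
| SpO₂ | 98 % | lactate | 1.0 mmol/L |
| temperature | 37.0 °C | GCS | 15 |

The original score derivations do not publish the sentinel values they
used; these are configurable in principle (they live in one module-level
table) but any choice inside the zero-point band of every score is
behaviorally identical.

Mean arterial pressure is taken as recorded when present; otherwise
derived as (SBP + 2·DBP)/3 when both pressures were observed; otherwise
imputed from the pressure sentinels. Blood urea nitrogen must carry an
explicit unit tag and is canonicalized to mmol/L with the factor 2.8
(so the threshold equivalence 7 mmol/L ↔ 19.6 mg/dL is exact; the
converted value is rounded at the 9th decimal because 19.6/2.8 lands one
ulp above 7 in binary floating point).

## Score tables and their printed defects

MEDS, CURB-65 and the REMS family are implemented from their published
tables, with all threshold comparisons following the printed inequality
strictly — in particular MEDS uses age **>** 65 while CURB-65 uses age
**≥** 65; the tables genuinely differ. The MEDS "tachypnea or hypoxia"
criterion is the printed disjunction RR > 20, oxygen by mask, or SpO₂
< 90 %.

The circulating REMS band table contains typographical gaps and
duplicates. Each is resolved toward the score's original derivation (the
APACHE II bands REMS abbreviates), and each resolution is unit-tested:

* heart rate 40–54 printed at both 2 and 3 points → 2 points is 55–69,
  3 points is 40–54;
* heart rate "<39" at 4 points leaves 39 unassigned → 4-point band is
  < 40;
* SpO₂ ">75" at 4 points read as < 75; ">90" at 0 points leaves 90
  unassigned → 0-point band is ≥ 90;
* age "55–64" / "66–74" leave 65 unassigned → 65 joins the 5-point band;
* respiratory-rate bands leave exactly 5 unassigned → 4-point band is
  ≤ 5; MAP bands leave exactly 49 unassigned → 4-point band is ≤ 49.

Band edges are defined on the printed integers; for fractional inputs the
implementation extends each band by its printed inequality direction.
Correctness is checked against an independently coded table oracle
(interval rows + linear scan) on 10,000 random records, and every
attainable total is verified constructively — note that MEDS totals 1
and 26 are arithmetically unattainable with criterion weights
{2,2,2,3,3,3,3,3,6}.

CURB-65's "confusion" and MEDS/mREMS "altered mental status" are kept as
separate fields: they are distinct chart findings, even though a given
abstraction workflow may record them identically.

## Sepsis classifier

SIRS criteria: temperature > 38 or < 36 °C; heart rate > 90/min;
respiratory rate > 20/min; WBC > 12 or < 4 ·10³/µL or bands > 10 %. The
PaCO₂ < 32 mmHg alternative for the respiratory criterion is not modeled
(no PaCO₂ field exists in the source data tables). Eligibility requires
≥ 2 criteria plus suspected or documented infection. Eligible patients
receive exactly one category by precedence: septic shock (MAP < 65 mmHg
or SBP < 90 after fluid bolus), then severe sepsis by lactate ≥ 4 mmol/L
(inclusive), then severe sepsis by recorded organ dysfunction. Organ
dysfunction is accepted as a recorded boolean rather than derived from
laboratory values, because the qualifying dysfunctions were never
enumerated in the source.

## ROC / AUC

Deaths are the positive class, fixed in one function
(`split_by_outcome`) so the orientation cannot silently invert. The AUC
is the tie-corrected Mann–Whitney statistic, computed via midranks;
severity scores are small integers, so ties dominate and the half-credit
convention is what makes the pair-count AUC equal the trapezoidal area
under the empirical ROC curve (asserted to 1e-12 on random instances
against an exhaustive pair-enumeration oracle).

The source report prints AUC confidence intervals without naming a
method, so two standard ones are provided and reported side by side:

* **DeLong** (default): structural-components variance
  `S10/m + S01/n`, normal-approximation CI truncated to [0, 1], with
  `z = Φ⁻¹(0.975)`. Verified against R's `pROC` DeLong implementation on
  a frozen fixture (variance agreement to 1e-10).
* **Stratified percentile bootstrap**: resampling within each outcome
  group, ≥ 1000 replicates, explicit seed required; bit-reproducible
  under a fixed seed.

A null-coverage acceptance check (500 replicates of identical
integer-score distributions at the study's 71/145 class sizes) verifies
the DeLong CI covers 0.5 at the nominal rate. Paired AUC-difference
tests and calibration metrics are out of scope: the analysis this
package models compares scores by overlapping CIs and reports
discrimination only. One source-internal inconsistency is worth
recording: the baseline mREMS AUC is printed as 0.62 in the results and
0.63 in the sensitivity analysis; neither value is "corrected" here.

## Cohort statistics

Proportions use the Wald interval `p ± 1.96·√(p(1−p)/n)`, truncated,
which reproduces the published mortality arithmetic from 71/216 (32.9 %,
lower bound 26.6 %). The computed upper bound is 39.1 % where the source
prints 39.2 % — a one-final-digit difference recorded as a source-side
rounding question and deliberately not matched. The Wilson interval is
available by flag for boundary cases (k = 0 or k = n), where Wald
degenerates. Quartiles are Tukey hinges (medians of the halves,
including the overall median when n is odd), matching SPSS-era clinical
reporting; the rule is isolated in `median_iqr` so alternates are a
one-line swap. Raw values are kept unrounded internally; report
formatting rounds to one decimal, half-up.

## Synthetic cohort generator

The generator's defaults encode, per outcome stratum (145 survivors, 71
deaths), the published baseline-table marginals: thirteen binary
prevalences, four vital-sign means with sds recovered from the 95 % CIs
of the mean as `halfwidth·√n/1.96`, and the age median/IQR. Age is
modeled log-normal, matched on the log scale (µ = ln median,
σ = log-IQR/1.349) — right-skewed as ED age distributions are; two
parameters reproduce the median and IQR width, not each quartile's
slight asymmetry.

Within a stratum variables are independent: the source publishes
marginals only, and no joint structure is invented. Mechanical
flag↔value consistency is nonetheless enforced by conditional sampling,
and checked exhaustively per cohort:

* "RR > 30" is nested inside "tachypnea or hypoxia" by comonotone
  coupling (one uniform drives both flags), keeping both marginals exact;
  the respiratory rate is then drawn from the matching conditional band
  ( > 30, 20–30, or ≤ 20 ) of the stratum's truncated normal.
* Patients outside the tachypnea/hypoxia stratum are drawn with SpO₂
  ≥ 90 and off supplemental oxygen; inside it, SpO₂ is unconstrained and
  supplemental oxygen is present with probability 0.3 (ambulance arrivals
  commonly arrive on oxygen).
* The "age > 65" flag is drawn as Bernoulli and the log-normal is
  truncated to the flag's side of 65, so the binary marginal recovers
  exactly *and* the quantile calibration holds.
* The hypotension flag drives the first-recorded pressures (flagged:
  SBP ∈ [70, 89.5], DBP ∈ [35, 59.5]; unflagged: SBP ≥ 90 and DBP ≥ 60
  from truncated normals). The shock flag populates the separate boolean
  "SBP < 90 after fluid bolus" — a post-resuscitation assessment with no
  numeric field of its own. The source table cannot have both rows drive
  the same pressure field (88–94 % shock vs 19–23 % hypotension), and
  this reading keeps every marginal exact; it also reflects the clinical
  distinction between arrival pressures and post-bolus response.
* Lab flags couple to values drawn from simple conditional families
  (shifted exponentials above the threshold, uniforms below), offset by
  more than the storage rounding granularity so a rounded value can never
  cross its threshold.

Open lower bounds are shifted by 0.06 (> half the 0.1 storage rounding
step) for the same reason. Fields absent from the published table —
temperature, WBC, lactate, organ dysfunction — are generated
outcome-independent (temperature N(38.2, 1.1) °C; WBC and lactate
log-normal with medians 13 ·10³/µL and 2.3 mmol/L), so no mortality
signal beyond the published marginals is invented. GCS is generated only
through the AMS flag (15 when absent, 9–14 when present), mirroring the
rationale for using mREMS: initial GCS is rarely charted in this
population. The table publishes no confusion row, so the generator
aliases confusion to the altered-mental-status draw.

The published table prints identical values (19.3 %/22.5 %) for its
"RR > 30" and "Hypotension" rows with different P values — likely a
transcription artifact; the defaults use the printed numbers unchanged.

`coupling_knob(spec, s)` linearly rescales every stratum separation
about the size-weighted pooled value: s = 0 removes all outcome signal
(AUC → 0.5), s = 1 is the identity, s > 1 exaggerates separation
(prevalences clipped to [0, 1]). This supports the signal-monotonicity
acceptance sweep.

**What passing tests do and do not show.** The generator recovers the
published marginals unbiasedly (checked to 3 Monte-Carlo SEs over 200
replicates) and produces internally consistent records; but real
physiology is correlated (shock, lactate, mentation and mortality travel
together), the real cohort's score-component correlations are unknown,
and the generator makes no attempt to impose them. Consequently the
published real-data AUCs (0.74 MEDS, 0.62 mREMS, 0.59 CURB-65) are not
reproduction targets — only qualitative behavior is asserted: AUC ≈ 0.5
at zero coupling, monotone growth with coupling strength, and (as a
reported, non-gating observation) MEDS out-discriminating CURB-65 at the
calibrated strength, which matches the published ordering. In practice
mean synthetic AUCs at strength 1 land near 0.76 (MEDS), 0.58 (mREMS)
and 0.60 (CURB-65), computed fresh by `scripts/acceptance.py`.

## Pipeline determinism

`full_run` derives every random stream (generator, bootstrap) from the
single configured seed, writes no timestamps, and serializes JSON with
sorted keys, so reruns with the same config are byte-identical — this is
itself an acceptance test. The manifest records the seed, a SHA-256 hash
of the semantic config (output paths excluded), package version, and
per-artifact checksums. Stage failures abort with a stage-named error.

## Problem sizes used in the checks

The statistical acceptance checks run at the study's native 216-patient
cohort size: 1,000 random instances for the AUC oracle equivalence, 500
replicates for DeLong null coverage, 200 replicates for generator
marginal recovery, and 50 seeds × 4 coupling strengths for the
monotonicity sweep — sizes at which the Monte-Carlo error of each check
is far below its decision threshold.

## Known limitations

* Single-timepoint model: no repeated vitals, no time-to-event outcome.
* PaCO₂-based SIRS and GCS-primary analyses are out of scope by design.
* The synthetic cohort's sepsis-category split (≈ 91 % shock at default
  calibration) is shock-heavier than the published 85 %/11 %/4 %: with
  MAP centered at 52–55 mmHg and an 88–94 % shock-flag prevalence, the
  marginals themselves imply near-universal shock; the published split
  is reproduced exactly only from its printed counts.
* Normal sentinels are a convention, not physiology; provenance flags
  exist precisely so downstream users can quantify imputation burden.
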