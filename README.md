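# sepscore

Severity-of-illness scoring and mortality-discrimination analysis for
septic emergency-department (ED) cohorts.

Rapid bedside scores are the standard way to stratify illness severity in
ED patients with severe sepsis or septic shock — for triage, for trial
comparability, and for benchmarking across sites. This package implements
four of them exactly as published, together with everything needed to
evaluate them against in-hospital mortality on a cohort:

* **MEDS** (Mortality in Emergency Department Sepsis): nine weighted
  criteria, total 0–27 — terminal illness (6), age > 65 (3),
  tachypnea/hypoxia (3), shock after fluid bolus (3), platelets
  < 150·10³/mm³ (3), bands > 5 % (3), nursing-home residence (2), lower
  respiratory infection (2), altered mental status (2).
* **REMS** (Rapid Emergency Medicine Score): six banded variables — age
  up to 6 points, heart rate, respiratory rate, MAP, SpO₂ and GCS up to 4
  each — total 0–26.
* **mREMS**: REMS with the GCS component replaced by a 1-point binary
  altered-mental-status flag (total 0–23), for cohorts where an initial
  GCS is rarely charted.
* **CURB-65**: confusion, urea > 7 mmol/L, respiratory rate > 30,
  hypotension (SBP < 90 or DBP < 60), age ≥ 65 — one point each, 0–5.

Around the calculators the package provides:

* the chart-abstraction **normal-imputation convention** (any unrecorded
  variable is resolved to a normal value, with per-field provenance, so
  that a missing field contributes 0 points to every score);
* a **SIRS-based sepsis classifier** (eligibility = ≥ 2 SIRS criteria +
  suspected infection; mutually exclusive categories septic shock →
  severe sepsis by lactate ≥ 4 mmol/L → severe sepsis by organ
  dysfunction);
* **ROC/AUC evaluation** with deaths as the positive class: tie-corrected
  Mann–Whitney AUC, `AUC = (#{pos > neg} + ½·#{pos = neg}) / (m·n)`,
  with DeLong and stratified-bootstrap 95 % CIs;
* **cohort statistics**: Wald/Wilson proportion CIs, Tukey-hinge
  median/IQR, survival stratified by score bin;
* a **synthetic-cohort generator** calibrated to published
  outcome-conditional marginals (145 survivors / 71 non-survivors), so
  the whole pipeline is testable with no patient data;
* sensitivity-analysis variants: `mrems_o2_adjusted` (SpO₂ band
  reassigned to the midpoint for patients hypoxic/tachypneic on
  supplemental oxygen) and `meds_objective` (MEDS without its two
  subjective criteria, max 19).

## Worked example

```python
from sepscore import default_spec, generate, resolve, compare_scores

records = [resolve(r) for r in generate(default_spec(), seed=2026)]
for res in compare_scores(records, ("MEDS", "mREMS", "CURB65")):
    print(f"{res.score_name:8s} AUC {res.auc:.3f} "
          f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
```

prints

```
MEDS     AUC 0.761 (95% CI 0.690-0.832)
CURB65   AUC 0.636 (95% CI 0.563-0.708)
mREMS    AUC 0.630 (95% CI 0.554-0.707)
```

i.e. on a cohort drawn from the calibrated marginals, the nine-variable
MEDS score discriminates in-hospital mortality best, and the two shorter
scores sit noticeably lower with overlapping confidence intervals.
Because the generator encodes marginals only (no between-variable
correlation), these AUCs characterize the synthetic conditions, not any
real cohort.

The `examples/` directory contains one short script per capability:
single-patient scoring with component breakdowns, cohort generation,
ROC comparison, the descriptive cohort report, and the sensitivity
variants.

## Command line

A thin CLI wraps the same library calls:

```bash
sepscore simulate --seed 7 --out cohort.csv
sepscore score cohort.csv --explain
sepscore evaluate cohort.csv --method delong
sepscore report cohort.csv --bins 3
sepscore full-run --seed 7 --outdir run/
```

`full-run` executes simulate → resolve → score → evaluate → report and
writes a deterministic artifact set (cohort, score table, AUC table,
summary text/JSON, manifest with seed, config hash and checksums);
rerunning with the same seed reproduces every artifact bit-exactly.

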