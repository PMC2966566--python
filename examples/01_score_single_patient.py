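"""Score one septic ED patient on all four severity scores.

Builds a patient from first-recorded ED observations — including two
fields that were never charted (GCS, lactate), which the resolution step
imputes as normal — and prints each score with its component breakdown.
"""

from sepscore import PatientRecord, TriState, resolve
from sepscore.severity_scores import SCORERS

patient = PatientRecord(
    id="ed-001",
    age=72,
    heart_rate=118,
    resp_rate=26,
    sbp=84,
    dbp=50,
    spo2=91,
    temp=38.9,
    wbc=15.2,
    bands_pct=7,
    platelets=132,
    bun=22.4, bun_unit="mg/dL",      # converted to 8 mmol/L internally
    altered_mental_status=TriState.YES,
    confusion=TriState.YES,
    nursing_home_resident=TriState.YES,
    lower_respiratory_infection=TriState.YES,
    shock_after_fluids=TriState.YES,
)

resolved = resolve(patient)
print(f"patient {resolved.id}: {resolved.n_imputed} fields imputed as normal")
imputed = [k for k, v in resolved.provenance.items() if v == "imputed_normal"]
print(f"  imputed: {', '.join(imputed)}")
print(f"  MAP derived from SBP/DBP: {resolved.map:.1f} mmHg\n")

for name in ("MEDS", "REMS", "mREMS", "CURB65"):
    result = SCORERS[name](resolved)
    print(f"{name}: {result.total}/{result.max_possible}")
    for c in result.components:
        if c.points:
            print(f"    +{c.points}  {c.variable}: {c.criterion}")

# A high MEDS total (>= 15 in the original stratification) marks the
# highest published mortality-risk group; CURB-65 >= 3 marks severe
# pneumonia.  The totals above come from first-recorded values only.
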