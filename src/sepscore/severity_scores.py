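"""Severity-of-illness scores for septic ED patients, plus the sepsis classifier.

Four scores are implemented exactly as tabulated in their published forms:

* **MEDS** (Mortality in Emergency Department Sepsis) — nine weighted
  criteria, 0–27 points.
* **REMS** (Rapid Emergency Medicine Score) — six banded variables
  (age up to 6 points; heart rate, respiratory rate, MAP, SpO2 and GCS up to
  4 points each), 0–26 points.
* **mREMS** — REMS with the Glasgow Coma Scale component replaced by a
  1-point binary altered-mental-status flag, 0–23 points, for cohorts where
  an initial GCS is rarely charted.
* **CURB-65** — five 1-point criteria (confusion, urea > 7 mmol/L,
  respiratory rate > 30, hypotension, age >= 65), 0–5 points.

Two sensitivity-analysis variants address known chart-abstraction artifacts:
``mrems_o2_adjusted`` re-scores the SpO2 band for patients whose saturation
was only ever recorded on supplemental oxygen, and ``meds_objective`` drops
the two subjective MEDS criteria (terminal illness, altered mental status).

The published REMS band table contains several typographical gaps and
duplicates; this module resolves each toward the score's original
derivation (the APACHE II bands REMS abbreviates).  Every resolution is
noted inline and unit-tested:

* heart rate 40–54 is printed in both the 2- and 3-point columns — 2 points
  is 55–69 and 3 points is 40–54;
* heart rate "<39" at 4 points leaves 39 unassigned — the 4-point band is
  < 40;
* SpO2 ">75" at 4 points is read as < 75, and ">90" at 0 points leaves 90
  unassigned — the 0-point band is >= 90;
* age bands 55–64 / "66–74" leave 65 unassigned — 65 belongs to the 5-point
  band (65–74);
* respiratory rate leaves exactly 5 unassigned — the 4-point band is <= 5;
* MAP leaves exactly 49 unassigned — the 4-point band is <= 49.

All other threshold comparisons follow the printed inequality strictly
(urea > 7, not >= 7; MEDS age > 65 but CURB-65 age >= 65 — the source
tables genuinely differ).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable

from .patient_model import ResolvedRecord

__all__ = [
    "ScoreComponent",
    "ScoreResult",
    "SepsisCategory",
    "SepsisClassification",
    "SCORE_NAMES",
    "SCORERS",
    "MAX_SCORES",
    "meds_score",
    "rems_score",
    "mrems_score",
    "curb65_score",
    "mrems_o2_adjusted",
    "meds_objective",
    "meds_tachypnea_or_hypoxia",
    "classify_sepsis",
    "score_record",
]


@dataclass(frozen=True)
class ScoreComponent:
    variable: str
    criterion: str   # human-readable description of the band/criterion met
    points: int


@dataclass(frozen=True)
class ScoreResult:
    """A score total with its per-variable point breakdown."""

    score_name: str
    total: int
    components: tuple[ScoreComponent, ...]
    max_possible: int

    def __post_init__(self) -> None:
        assert self.total == sum(c.points for c in self.components)
        assert 0 <= self.total <= self.max_possible

    def component(self, variable: str) -> ScoreComponent:
        for c in self.components:
            if c.variable == variable:
                return c
        raise KeyError(variable)


MAX_SCORES = {
    "MEDS": 27,
    "REMS": 26,
    "mREMS": 23,
    "CURB65": 5,
    "mREMS_o2adj": 23,
    "MEDS_objective": 19,
}

SCORE_NAMES = tuple(MAX_SCORES)


# ---------------------------------------------------------------------------
# MEDS

def meds_tachypnea_or_hypoxia(r: ResolvedRecord) -> bool:
    """The MEDS respiratory criterion: RR > 20, O2 by mask, or SpO2 < 90%."""
    return r.resp_rate > 20 or r.on_supplemental_o2 or r.spo2 < 90


def _meds_components(r: ResolvedRecord) -> list[ScoreComponent]:
    crit: list[tuple[str, str, int, bool]] = [
        ("terminal_illness", "rapidly fatal illness", 6, r.terminal_illness),
        ("age", "age > 65 years", 3, r.age > 65),
        ("tachypnea_or_hypoxia", "RR > 20, O2 by mask, or SpO2 < 90%", 3,
         meds_tachypnea_or_hypoxia(r)),
        ("shock", "SBP < 90 after IVF bolus", 3, r.shock_after_fluids),
        ("thrombocytopenia", "platelets < 150,000/mm3", 3, r.platelets < 150),
        ("bandemia", "bands > 5%", 3, r.bands_pct > 5),
        ("nursing_home_resident", "nursing home resident", 2,
         r.nursing_home_resident),
        ("lower_respiratory_infection", "lower respiratory tract infection", 2,
         r.lower_respiratory_infection),
        ("altered_mental_status", "altered mental status", 2,
         r.altered_mental_status),
    ]
    return [
        ScoreComponent(name, desc if met else "criterion not met",
                       pts if met else 0)
        for name, desc, pts, met in crit
    ]


def meds_score(r: ResolvedRecord) -> ScoreResult:
    """MEDS score: nine weighted criteria, 0–27 points."""
    comps = _meds_components(r)
    return ScoreResult("MEDS", sum(c.points for c in comps), tuple(comps), 27)


def meds_objective(r: ResolvedRecord) -> ScoreResult:
    """MEDS without its two subjective criteria (terminal illness, AMS); 0–19.

    Used as a sensitivity analysis: both omitted variables require judgement
    calls that are hard to reproduce from chart review.
    """
    comps = [c for c in _meds_components(r)
             if c.variable not in ("terminal_illness", "altered_mental_status")]
    return ScoreResult("MEDS_objective", sum(c.points for c in comps),
                       tuple(comps), 19)


# ---------------------------------------------------------------------------
# REMS / mREMS band lookups

def _age_points(age: float) -> int:
    if age < 45:
        return 0
    if age < 55:
        return 2
    if age < 65:
        return 3
    if age <= 74:  # printed "66-74"; 65 belongs here (see module docstring)
        return 5
    return 6


def _hr_points(hr: float) -> int:
    if hr < 40:    # printed "<39"; 39 scores 4
        return 4
    if hr < 55:    # 40-54: printed in two columns; original assigns 3
        return 3
    if hr < 70:    # 55-69
        return 2
    if hr < 110:   # 70-109
        return 0
    if hr < 140:   # 110-139
        return 2
    if hr < 180:   # 140-179
        return 3
    return 4       # >179


def _rr_points(rr: float) -> int:
    if rr <= 5:    # printed "<5"; 5 scores 4
        return 4
    if rr < 10:    # 6-9
        return 2
    if rr < 12:    # 10-11
        return 1
    if rr <= 24:   # 12-24
        return 0
    if rr < 35:    # 25-34
        return 1
    if rr <= 49:   # 35-49
        return 3
    return 4       # >49


def _map_points(map_: float) -> int:
    if map_ <= 49:  # printed "<49"; 49 scores 4
        return 4
    if map_ < 70:   # 50-69
        return 2
    if map_ < 110:  # 70-109
        return 0
    if map_ < 130:  # 110-129
        return 2
    if map_ <= 159:  # 130-159
        return 3
    return 4        # >159


def _spo2_points(spo2: float) -> int:
    if spo2 < 75:   # printed ">75"; read as <75
        return 4
    if spo2 <= 85:  # 75-85
        return 3
    if spo2 < 90:   # 86-89; printed ">90" at 0 points, 90 scores 0
        return 1
    return 0


def _gcs_points(gcs: float) -> int:
    if gcs < 5:
        return 4
    if gcs <= 7:
        return 3
    if gcs <= 10:
        return 2
    if gcs <= 13:
        return 1
    return 0


def _rems_vital_components(r: ResolvedRecord) -> list[ScoreComponent]:
    return [
        ScoreComponent("age", f"age {r.age:g} y", _age_points(r.age)),
        ScoreComponent("heart_rate", f"HR {r.heart_rate:g}/min",
                       _hr_points(r.heart_rate)),
        ScoreComponent("resp_rate", f"RR {r.resp_rate:g}/min",
                       _rr_points(r.resp_rate)),
        ScoreComponent("map", f"MAP {r.map:g} mmHg", _map_points(r.map)),
        ScoreComponent("spo2", f"SpO2 {r.spo2:g}%", _spo2_points(r.spo2)),
    ]


def rems_score(r: ResolvedRecord) -> ScoreResult:
    """Original REMS with the Glasgow Coma Scale component; 0–26 points."""
    comps = _rems_vital_components(r)
    comps.append(ScoreComponent("gcs", f"GCS {r.gcs:g}", _gcs_points(r.gcs)))
    return ScoreResult("REMS", sum(c.points for c in comps), tuple(comps), 26)


def mrems_score(r: ResolvedRecord) -> ScoreResult:
    """Modified REMS: GCS replaced by a 1-point binary AMS flag; 0–23 points."""
    comps = _rems_vital_components(r)
    comps.append(
        ScoreComponent("altered_mental_status",
                       "AMS present" if r.altered_mental_status else "AMS absent",
                       1 if r.altered_mental_status else 0)
    )
    return ScoreResult("mREMS", sum(c.points for c in comps), tuple(comps), 23)


def mrems_o2_adjusted(r: ResolvedRecord) -> ScoreResult:
    """mREMS with the supplemental-oxygen SpO2 correction; 0–23 points.

    Saturations charted only on supplemental oxygen falsely lower the SpO2
    band.  If the mREMS SpO2 component is 0 or 1 while the patient is
    hypoxic or tachypneic by the MEDS criterion, the SpO2 component is
    reassigned the band midpoint of 2.
    """
    base = mrems_score(r)
    comps = list(base.components)
    for i, c in enumerate(comps):
        if c.variable == "spo2" and c.points in (0, 1) \
                and meds_tachypnea_or_hypoxia(r):
            comps[i] = ScoreComponent(
                "spo2", "reassigned midpoint (hypoxic/tachypneic on O2)", 2)
    return ScoreResult("mREMS_o2adj", sum(c.points for c in comps),
                       tuple(comps), 23)


# ---------------------------------------------------------------------------
# CURB-65

def curb65_score(r: ResolvedRecord) -> ScoreResult:
    """CURB-65: five 1-point criteria, 0–5 points.  BUN in mmol/L."""
    crit = [
        ("confusion", "confusion", r.confusion),
        ("urea", "urea > 7 mmol/L (19.6 mg/dL)", r.bun > 7),
        ("resp_rate", "RR > 30 breaths/min", r.resp_rate > 30),
        ("hypotension", "SBP < 90 or DBP < 60 mmHg",
         r.sbp < 90 or r.dbp < 60),
        ("age", "age >= 65 years", r.age >= 65),
    ]
    comps = [
        ScoreComponent(name, desc if met else "criterion not met",
                       1 if met else 0)
        for name, desc, met in crit
    ]
    return ScoreResult("CURB65", sum(c.points for c in comps), tuple(comps), 5)


SCORERS: dict[str, Callable[[ResolvedRecord], ScoreResult]] = {
    "MEDS": meds_score,
    "REMS": rems_score,
    "mREMS": mrems_score,
    "CURB65": curb65_score,
    "mREMS_o2adj": mrems_o2_adjusted,
    "MEDS_objective": meds_objective,
}


def score_record(r: ResolvedRecord, score_name: str) -> ScoreResult:
    try:
        return SCORERS[score_name](r)
    except KeyError:
        raise KeyError(
            f"unknown score {score_name!r}; available: {', '.join(SCORERS)}"
        ) from None


# ---------------------------------------------------------------------------
# Sepsis eligibility and severity category

class SepsisCategory(str, enum.Enum):
    SEPTIC_SHOCK = "septic_shock"
    SEVERE_SEPSIS_LACTATE = "severe_sepsis_lactate"
    SEVERE_SEPSIS_ORGAN_DYSFUNCTION = "severe_sepsis_organ_dysfunction"
    NOT_QUALIFYING = "not_qualifying"


@dataclass(frozen=True)
class SepsisClassification:
    eligible: bool
    category: SepsisCategory
    sirs_flags: tuple[bool, bool, bool, bool]  # temp, HR, RR, WBC/bands

    @property
    def n_sirs(self) -> int:
        return sum(self.sirs_flags)


def classify_sepsis(
    r: ResolvedRecord, infection_suspected: bool = True
) -> SepsisClassification:
    """SIRS-based eligibility plus the mutually exclusive severity category.

    SIRS criteria: (a) temperature > 38 or < 36 C; (b) heart rate > 90/min;
    (c) respiratory rate > 20/min (the PaCO2 alternative is not modeled —
    no PaCO2 field exists in the data model); (d) WBC > 12 or < 4 (10^3/uL)
    or bands > 10%.  A patient is eligible with >= 2 criteria and suspected
    or documented infection.

    Eligible patients are assigned exactly one category, in precedence order:
    septic shock (MAP < 65 mmHg or SBP < 90 after fluid bolus), then severe
    sepsis by lactate >= 4 mmol/L (inclusive), then severe sepsis by
    recorded organ dysfunction.
    """
    sirs = (
        r.temp > 38 or r.temp < 36,
        r.heart_rate > 90,
        r.resp_rate > 20,
        r.wbc > 12 or r.wbc < 4 or r.bands_pct > 10,
    )
    eligible = sum(sirs) >= 2 and infection_suspected
    if not eligible:
        category = SepsisCategory.NOT_QUALIFYING
    elif r.map < 65 or r.shock_after_fluids:
        category = SepsisCategory.SEPTIC_SHOCK
    elif r.lactate >= 4:
        category = SepsisCategory.SEVERE_SEPSIS_LACTATE
    elif r.organ_dysfunction:
        category = SepsisCategory.SEVERE_SEPSIS_ORGAN_DYSFUNCTION
    else:
        category = SepsisCategory.NOT_QUALIFYING
    return SepsisClassification(eligible, category, sirs)
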