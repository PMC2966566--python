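"""Synthetic septic-ED cohorts calibrated to printed outcome-conditional marginals.

The study this package models published no patient-level data — only the
outcome-conditional *marginal* distributions of its baseline table: binary
prevalences among the 145 survivors and 71 non-survivors, first-recorded
vital-sign means with 95% CIs of the mean, and the age median/IQR per
stratum.  :func:`default_spec` encodes exactly those numbers;
:func:`generate` draws cohorts from them so that scoring, ROC and
reporting stages are testable end to end with no external data.

Within an outcome stratum, variables are drawn independently: the source
table gives marginals only, and no joint structure is invented.  The one
exception is mechanical consistency between a drawn flag and the value it
summarizes (a patient flagged "RR > 30" really has a respiratory rate
above 30, a flagged "age > 65" patient really is older than 65, and so
on), enforced by conditional sampling.  Because real scores aggregate
*correlated* physiology, cohorts drawn from marginals alone are not
expected to reproduce the study's real-data AUCs numerically — only
qualitative behavior (signal ordering, monotone response to the coupling
strength) is asserted anywhere in this package.

Standard deviations of the vital signs are recovered from the printed 95%
CIs of the mean as ``halfwidth * sqrt(n) / 1.96`` with n the stratum size.
Age uses a log-normal matched to the printed median/IQR on the log scale
(right skew typical of ED age distributions), truncated to the drawn side
of the 65-year threshold so the "age > 65" prevalence is recovered exactly
as well.

The printed table carries identical values (19.3% / 22.5%) for its
"RR > 30" and "Hypotension" rows with different P values — likely a
transcription artifact in the source; the defaults use the printed numbers
as-is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .patient_model import PatientRecord, Sex, TriState

__all__ = [
    "VitalSpec",
    "AgeSpec",
    "CohortSpec",
    "default_spec",
    "generate",
    "generate_with_flags",
    "coupling_knob",
    "check_consistency",
    "BINARY_FIELDS",
]

_Z = 1.96
_Q75 = float(ndtri(0.75))  # 0.6745, IQR halfwidth of a standard normal
# Stored values are rounded to 1 decimal; open lower bounds are shifted by
# more than half that granularity so rounding cannot land on the threshold
# and break a strict inequality.
_EPS = 0.06

#: Binary fields carried by the spec, in canonical draw order.
#: (surv %, non-surv %) defaults are the printed baseline-table rows.
BINARY_FIELDS = (
    "altered_mental_status",
    "nursing_home_resident",
    "lower_respiratory_infection",
    "age_gt65",
    "bands_gt5",
    "platelets_lt150",
    "shock_after_fluids",
    "tachypnea_or_hypoxia",
    "terminal_illness",
    "urea_gt7",
    "rr_gt30",
    "hypotension",
    "male",
)

_DEFAULT_BINARY = {
    "altered_mental_status": (0.61, 0.775),
    "nursing_home_resident": (0.621, 0.549),
    "lower_respiratory_infection": (0.407, 0.493),
    "age_gt65": (0.572, 0.662),
    "bands_gt5": (0.40, 0.577),
    "platelets_lt150": (0.179, 0.324),
    "shock_after_fluids": (0.883, 0.944),
    "tachypnea_or_hypoxia": (0.697, 0.887),
    "terminal_illness": (0.048, 0.324),
    "urea_gt7": (0.855, 0.873),
    "rr_gt30": (0.193, 0.225),
    # printed identically to rr_gt30 (see module docstring)
    "hypotension": (0.193, 0.225),
    "male": (0.51, 0.493),
}

#: (mean, ci_low, ci_high) per stratum, physiologic truncation bounds.
_DEFAULT_VITALS = {
    "heart_rate": ((114.0, 109.0, 119.0), (114.0, 107.0, 120.0), 20.0, 250.0),
    "resp_rate": ((24.0, 23.0, 26.0), (25.0, 22.0, 27.0), 4.0, 80.0),
    "map": ((55.0, 52.0, 58.0), (52.0, 48.0, 57.0), 20.0, 200.0),
    "spo2": ((94.0, 92.0, 95.0), (93.0, 91.0, 95.0), 50.0, 100.0),
}

_DEFAULT_AGE = {
    "survivors": (69.0, 58.0, 78.0),
    "deaths": (77.0, 60.0, 86.0),
}


@dataclass(frozen=True)
class VitalSpec:
    """Truncated-normal parameters for one vital, by outcome stratum."""

    mean_surv: float
    sd_surv: float
    mean_death: float
    sd_death: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd_surv <= 0 or self.sd_death <= 0:
            raise ValueError("vital sd must be positive")
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must satisfy lo < hi")

    def params(self, survived: bool) -> tuple[float, float]:
        return ((self.mean_surv, self.sd_surv) if survived
                else (self.mean_death, self.sd_death))


@dataclass(frozen=True)
class AgeSpec:
    """Log-normal age model matched to (median, q1, q3), by stratum."""

    surv: tuple[float, float, float]
    death: tuple[float, float, float]
    lo: float = 18.0
    hi: float = 110.0

    def log_params(self, survived: bool) -> tuple[float, float]:
        med, q1, q3 = self.surv if survived else self.death
        mu = float(np.log(med))
        sigma = float((np.log(q3) - np.log(q1)) / (2.0 * _Q75))
        return mu, sigma


@dataclass(frozen=True)
class CohortSpec:
    """Outcome-conditional distribution parameters driving the generator."""

    n_survivors: int = 145
    n_deaths: int = 71
    binary: dict[str, tuple[float, float]] = field(default_factory=dict)
    vitals: dict[str, VitalSpec] = field(default_factory=dict)
    age: AgeSpec = field(default_factory=lambda: AgeSpec(
        _DEFAULT_AGE["survivors"], _DEFAULT_AGE["deaths"]))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivors <= 0 or self.n_deaths <= 0:
            raise ValueError("stratum sizes must be positive")
        for name, (ps, pd_) in self.binary.items():
            if not (0.0 <= ps <= 1.0 and 0.0 <= pd_ <= 1.0):
                raise ValueError(
                    f"prevalence for {name!r} outside [0, 1]: {(ps, pd_)}")
        missing = set(BINARY_FIELDS) - set(self.binary)
        if missing:
            raise ValueError(f"spec missing binary fields: {sorted(missing)}")
        if set(self.vitals) != set(_DEFAULT_VITALS):
            raise ValueError(
                f"spec must define vitals {sorted(_DEFAULT_VITALS)}")

    @property
    def n_total(self) -> int:
        return self.n_survivors + self.n_deaths


def _sd_from_ci(mean_ci: tuple[float, float, float], n: int) -> float:
    _, lo, hi = mean_ci
    halfwidth = (hi - lo) / 2.0
    return halfwidth * np.sqrt(n) / _Z


def default_spec(
    n_survivors: int = 145, n_deaths: int = 71, seed: int = 0
) -> CohortSpec:
    """The spec carrying every printed baseline-table marginal.

    Vital-sign sds are derived from the printed 95% CIs of the mean at the
    *default* stratum sizes (145/71), independent of the requested cohort
    size — they characterize the population, not the sample drawn.
    """
    vitals = {
        name: VitalSpec(
            mean_surv=s[0], sd_surv=_sd_from_ci(s, 145),
            mean_death=d[0], sd_death=_sd_from_ci(d, 71),
            lo=lo, hi=hi,
        )
        for name, (s, d, lo, hi) in _DEFAULT_VITALS.items()
    }
    return CohortSpec(
        n_survivors=n_survivors,
        n_deaths=n_deaths,
        binary=dict(_DEFAULT_BINARY),
        vitals=vitals,
        seed=seed,
    )


def _truncnorm(u: np.ndarray, mean, sd, lo, hi) -> np.ndarray:
    """Inverse-CDF truncated normal; accepts array bounds for conditional draws."""
    a = ndtr((np.asarray(lo) - mean) / sd)
    b = ndtr((np.asarray(hi) - mean) / sd)
    return mean + sd * ndtri(a + u * (b - a))


# Fixed nuisance distributions for fields absent from the printed table;
# deliberately outcome-independent so no mortality signal is invented.
_TEMP_MEAN, _TEMP_SD = 38.2, 1.1          # deg C, febrile sepsis cohort
_WBC_LOG_MED, _WBC_LOG_SD = np.log(13.0), 0.45   # 10^3/uL
_LACT_LOG_MED, _LACT_LOG_SD = np.log(2.3), 0.60  # mmol/L
_P_ORGAN_DYSFUNCTION = 0.5
_P_O2_GIVEN_TACH = 0.3   # arrival on supplemental oxygen, common via EMS


def _generate_stratum(
    rng: np.random.Generator,
    spec: CohortSpec,
    survived: bool,
    n: int,
    id_prefix: str,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    col = 0 if survived else 1
    p = {name: spec.binary[name][col] for name in BINARY_FIELDS}

    # RR>30 implies the tachypnea/hypoxia criterion: comonotone coupling
    # (one uniform drives both flags) keeps both marginals exact while
    # guaranteeing the nesting.
    u_resp = rng.random(n)
    rr30 = u_resp < min(p["rr_gt30"], p["tachypnea_or_hypoxia"])
    tach = u_resp < max(p["rr_gt30"], p["tachypnea_or_hypoxia"])

    flags = {"rr_gt30": rr30, "tachypnea_or_hypoxia": tach}
    for name in BINARY_FIELDS:
        if name not in flags:
            flags[name] = rng.random(n) < p[name]

    hr_mean, hr_sd = spec.vitals["heart_rate"].params(survived)
    hr_lo, hr_hi = spec.vitals["heart_rate"].lo, spec.vitals["heart_rate"].hi
    heart_rate = _truncnorm(rng.random(n), hr_mean, hr_sd, hr_lo, hr_hi)

    rr_mean, rr_sd = spec.vitals["resp_rate"].params(survived)
    rr_spec = spec.vitals["resp_rate"]
    rr_lo = np.where(rr30, 30.0 + _EPS,
                     np.where(tach, 20.0 + _EPS, rr_spec.lo))
    # (upper bounds are closed; rounding toward them cannot flip a flag)
    rr_hi = np.where(rr30, rr_spec.hi, np.where(tach, 30.0, 20.0))
    resp_rate = _truncnorm(rng.random(n), rr_mean, rr_sd, rr_lo, rr_hi)

    map_spec = spec.vitals["map"]
    map_mean, map_sd = map_spec.params(survived)
    map_ = _truncnorm(rng.random(n), map_mean, map_sd, map_spec.lo, map_spec.hi)

    # Patients outside the tachypnea/hypoxia stratum must satisfy SpO2 >= 90
    # (and are off supplemental O2); inside it the saturation is free.
    sp_spec = spec.vitals["spo2"]
    sp_mean, sp_sd = sp_spec.params(survived)
    sp_lo = np.where(tach, sp_spec.lo, 90.0)
    spo2 = _truncnorm(rng.random(n), sp_mean, sp_sd, sp_lo, sp_spec.hi)
    on_o2 = tach & (rng.random(n) < _P_O2_GIVEN_TACH)

    # First-recorded blood pressures follow the hypotension flag (SBP < 90
    # or DBP < 60); the shock flag is the separate post-fluid-bolus
    # assessment and has no numeric field of its own.
    hypo = flags["hypotension"]
    u1, u2 = rng.random(n), rng.random(n)
    sbp = np.where(hypo, 70.0 + 19.5 * u1,
                   _truncnorm(u1, 115.0, 15.0, 90.0, 200.0))
    dbp = np.where(hypo, 35.0 + 24.5 * u2,
                   _truncnorm(u2, 72.0, 8.0, 60.0, 120.0))

    mu, sigma = spec.age.log_params(survived)
    over65 = flags["age_gt65"]
    age_lo = np.where(over65, np.log(65.0 + _EPS), np.log(spec.age.lo))
    age_hi = np.where(over65, np.log(spec.age.hi), np.log(65.0))
    age = np.exp(_truncnorm(rng.random(n), mu, sigma, age_lo, age_hi))

    u = rng.random(n)
    bands = np.where(flags["bands_gt5"],
                     np.minimum(5.1 - 8.0 * np.log1p(-u), 60.0), 5.0 * u)
    u = rng.random(n)
    platelets = np.where(flags["platelets_lt150"],
                         30.0 + 119.0 * u, 150.0 + 300.0 * u)
    u = rng.random(n)
    bun = np.where(flags["urea_gt7"],
                   np.minimum(7.1 - 6.0 * np.log1p(-u), 60.0), 2.0 + 5.0 * u)

    wbc = np.clip(np.exp(rng.normal(_WBC_LOG_MED, _WBC_LOG_SD, n)), 0.5, 80.0)
    temp = np.clip(rng.normal(_TEMP_MEAN, _TEMP_SD, n), 34.0, 42.0)
    lactate = np.clip(
        np.exp(rng.normal(_LACT_LOG_MED, _LACT_LOG_SD, n)), 0.3, 20.0)
    organ_dys = rng.random(n) < _P_ORGAN_DYSFUNCTION

    # GCS only via the AMS flag (the primary analysis uses mREMS precisely
    # because initial GCS is rarely charted in this population).
    gcs_if_ams = rng.integers(9, 15, n)
    gcs = np.where(flags["altered_mental_status"], gcs_if_ams, 15)

    def tri(x: bool) -> TriState:
        return TriState.YES if x else TriState.NO

    records = []
    for i in range(n):
        records.append(PatientRecord(
            id=f"{id_prefix}{i + 1:04d}",
            age=round(float(age[i]), 1),
            sex=Sex.MALE if flags["male"][i] else Sex.FEMALE,
            heart_rate=round(float(heart_rate[i]), 1),
            resp_rate=round(float(resp_rate[i]), 1),
            sbp=round(float(sbp[i]), 1),
            dbp=round(float(dbp[i]), 1),
            map=round(float(map_[i]), 1),
            spo2=round(float(spo2[i]), 1),
            temp=round(float(temp[i]), 1),
            gcs=int(gcs[i]),
            altered_mental_status=tri(flags["altered_mental_status"][i]),
            confusion=tri(flags["altered_mental_status"][i]),
            nursing_home_resident=tri(flags["nursing_home_resident"][i]),
            lower_respiratory_infection=tri(
                flags["lower_respiratory_infection"][i]),
            terminal_illness=tri(flags["terminal_illness"][i]),
            shock_after_fluids=tri(flags["shock_after_fluids"][i]),
            on_supplemental_o2=tri(bool(on_o2[i])),
            wbc=round(float(wbc[i]), 1),
            bands_pct=round(float(bands[i]), 1),
            platelets=round(float(platelets[i]), 0),
            bun=round(float(bun[i]), 2),
            bun_unit="mmol/L",
            lactate=round(float(lactate[i]), 2),
            organ_dysfunction=tri(bool(organ_dys[i])),
            survived_to_discharge=survived,
        ))
    flag_df = pd.DataFrame({k: flags[k] for k in BINARY_FIELDS})
    flag_df.insert(0, "id", [r.id for r in records])
    flag_df["survived"] = survived
    return records, flag_df


def generate_with_flags(
    spec: CohortSpec, seed: Optional[int] = None
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Like :func:`generate`, also returning the latent flag draws per patient
    (for marginal-recovery and consistency checking)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    surv, f_s = _generate_stratum(rng, spec, True, spec.n_survivors, "S")
    died, f_d = _generate_stratum(rng, spec, False, spec.n_deaths, "D")
    flags = pd.concat([f_s, f_d], ignore_index=True)
    return surv + died, flags


def generate(spec: CohortSpec, seed: Optional[int] = None) -> list[PatientRecord]:
    """Draw a synthetic cohort: ``n_survivors + n_deaths`` records with fixed
    outcomes, reproducible bit-for-bit under a fixed spec and seed."""
    records, _ = generate_with_flags(spec, seed=seed)
    return records


def coupling_knob(spec: CohortSpec, strength: float) -> CohortSpec:
    """Rescale the survivor/non-survivor separation of every marginal.

    ``strength`` 0 collapses both strata onto the size-weighted pooled
    value (no outcome signal, all AUCs ~ 0.5); 1 is the identity; values
    above 1 exaggerate the separation (prevalences clipped to [0, 1]).
    Standard deviations and truncation bounds are untouched.
    """
    if strength < 0:
        raise ValueError(f"coupling strength must be >= 0, got {strength}")
    if strength == 1.0:
        return spec
    w_s = spec.n_survivors / spec.n_total
    w_d = spec.n_deaths / spec.n_total

    def pull(ps: float, pd_: float, clip01: bool) -> tuple[float, float]:
        pooled = w_s * ps + w_d * pd_
        a, b = pooled + strength * (ps - pooled), pooled + strength * (pd_ - pooled)
        if clip01:
            a, b = min(max(a, 0.0), 1.0), min(max(b, 0.0), 1.0)
        return a, b

    binary = {k: pull(*v, clip01=True) for k, v in spec.binary.items()}
    vitals = {}
    for name, v in spec.vitals.items():
        m_s, m_d = pull(v.mean_surv, v.mean_death, clip01=False)
        vitals[name] = dataclasses.replace(v, mean_surv=m_s, mean_death=m_d)
    log_s = np.log(spec.age.surv)
    log_d = np.log(spec.age.death)
    pooled = w_s * log_s + w_d * log_d
    age = AgeSpec(
        surv=tuple(np.exp(pooled + strength * (log_s - pooled))),
        death=tuple(np.exp(pooled + strength * (log_d - pooled))),
        lo=spec.age.lo, hi=spec.age.hi,
    )
    return dataclasses.replace(spec, binary=binary, vitals=vitals, age=age)


def check_consistency(
    records: Sequence[PatientRecord], flags: pd.DataFrame
) -> list[str]:
    """Exhaustively verify flag <-> value coupling; returns violation messages.

    An empty list means every record is internally consistent with its
    latent draws.
    """
    problems: list[str] = []
    for r, (_, f) in zip(records, flags.iterrows(), strict=True):
        checks = {
            "rr_gt30": (r.resp_rate > 30) == f["rr_gt30"],
            "tachypnea_or_hypoxia": (
                (r.resp_rate > 20 or r.on_supplemental_o2 is TriState.YES
                 or r.spo2 < 90) == f["tachypnea_or_hypoxia"]),
            "hypotension": (
                (r.sbp < 90 or r.dbp < 60) == f["hypotension"]),
            "age_gt65": (r.age > 65) == f["age_gt65"],
            "bands_gt5": (r.bands_pct > 5) == f["bands_gt5"],
            "platelets_lt150": (r.platelets < 150) == f["platelets_lt150"],
            "urea_gt7": (r.bun_mmol() > 7) == f["urea_gt7"],
            "gcs_vs_ams": (
                (r.gcs < 15) == f["altered_mental_status"]),
            "shock_after_fluids": (
                (r.shock_after_fluids is TriState.YES)
                == f["shock_after_fluids"]),
            "terminal_illness": (
                (r.terminal_illness is TriState.YES) == f["terminal_illness"]),
            "nursing_home_resident": (
                (r.nursing_home_resident is TriState.YES)
                == f["nursing_home_resident"]),
            "lower_respiratory_infection": (
                (r.lower_respiratory_infection is TriState.YES)
                == f["lower_respiratory_infection"]),
            "altered_mental_status": (
                (r.altered_mental_status is TriState.YES)
                == f["altered_mental_status"]),
            "male": ((r.sex is Sex.MALE) == f["male"]),
        }
        for name, ok in checks.items():
            if not ok:
                problems.append(f"{r.id}: {name} inconsistent")
    return problems
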