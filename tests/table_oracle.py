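"""Independently coded brute-force oracles for the score tables and the AUC.

The band tables below are transcribed directly as (lo, hi, points) rows
with inclusive integer bounds (None = unbounded) and looked up by linear
scan — a deliberately different representation from the package's
threshold chains, so agreement between the two is informative.
"""

from __future__ import annotations

# corrected REMS bands, inclusive integer intervals
REMS_BANDS = {
    "age": [(None, 44, 0), (45, 54, 2), (55, 64, 3), (65, 74, 5),
            (75, None, 6)],
    "heart_rate": [(None, 39, 4), (40, 54, 3), (55, 69, 2), (70, 109, 0),
                   (110, 139, 2), (140, 179, 3), (180, None, 4)],
    "resp_rate": [(None, 5, 4), (6, 9, 2), (10, 11, 1), (12, 24, 0),
                  (25, 34, 1), (35, 49, 3), (50, None, 4)],
    "map": [(None, 49, 4), (50, 69, 2), (70, 109, 0), (110, 129, 2),
            (130, 159, 3), (160, None, 4)],
    "spo2": [(None, 74, 4), (75, 85, 3), (86, 89, 1), (90, None, 0)],
    "gcs": [(None, 4, 4), (5, 7, 3), (8, 10, 2), (11, 13, 1),
            (14, None, 0)],
}


def band_lookup(variable: str, value: float) -> int:
    for lo, hi, pts in REMS_BANDS[variable]:
        if (lo is None or value >= lo) and (hi is None or value <= hi):
            return pts
    raise AssertionError(f"no band for {variable}={value}")


def rems_oracle(r) -> int:
    return sum(band_lookup(v, getattr(r, v))
               for v in ("age", "heart_rate", "resp_rate", "map", "spo2",
                         "gcs"))


def mrems_oracle(r) -> int:
    total = sum(band_lookup(v, getattr(r, v))
                for v in ("age", "heart_rate", "resp_rate", "map", "spo2"))
    return total + (1 if r.altered_mental_status else 0)


def meds_oracle(r) -> int:
    total = 0
    total += 6 if r.terminal_illness else 0
    total += 3 if r.age > 65 else 0
    total += 3 if (r.resp_rate > 20 or r.on_supplemental_o2
                   or r.spo2 < 90) else 0
    total += 3 if r.shock_after_fluids else 0
    total += 3 if r.platelets < 150 else 0
    total += 3 if r.bands_pct > 5 else 0
    total += 2 if r.nursing_home_resident else 0
    total += 2 if r.lower_respiratory_infection else 0
    total += 2 if r.altered_mental_status else 0
    return total


def meds_objective_oracle(r) -> int:
    total = 0
    total += 3 if r.age > 65 else 0
    total += 3 if (r.resp_rate > 20 or r.on_supplemental_o2
                   or r.spo2 < 90) else 0
    total += 3 if r.shock_after_fluids else 0
    total += 3 if r.platelets < 150 else 0
    total += 3 if r.bands_pct > 5 else 0
    total += 2 if r.nursing_home_resident else 0
    total += 2 if r.lower_respiratory_infection else 0
    return total


def curb65_oracle(r) -> int:
    return sum([
        1 if r.confusion else 0,
        1 if r.bun > 7 else 0,
        1 if r.resp_rate > 30 else 0,
        1 if (r.sbp < 90 or r.dbp < 60) else 0,
        1 if r.age >= 65 else 0,
    ])


def mrems_o2_oracle(r) -> int:
    spo2_pts = band_lookup("spo2", r.spo2)
    meds_resp = r.resp_rate > 20 or r.on_supplemental_o2 or r.spo2 < 90
    if spo2_pts in (0, 1) and meds_resp:
        spo2_pts = 2
    total = sum(band_lookup(v, getattr(r, v))
                for v in ("age", "heart_rate", "resp_rate", "map"))
    return total + spo2_pts + (1 if r.altered_mental_status else 0)


ORACLES = {
    "MEDS": meds_oracle,
    "REMS": rems_oracle,
    "mREMS": mrems_oracle,
    "CURB65": curb65_oracle,
    "mREMS_o2adj": mrems_o2_oracle,
    "MEDS_objective": meds_objective_oracle,
}


def auc_pair_count(pos, neg) -> float:
    """Exhaustive pair enumeration with half credit for ties."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
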