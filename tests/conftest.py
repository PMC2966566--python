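import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sepscore.patient_model import PatientRecord, TriState, resolve

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_patient(**kwargs) -> PatientRecord:
    kwargs.setdefault("id", "p1")
    return PatientRecord(**kwargs)


def make_resolved(**kwargs):
    """An all-normal resolved record with selected fields overridden."""
    return resolve(make_patient(**kwargs))


@pytest.fixture
def normal_adult():
    """A fully observed, entirely normal 40-year-old."""
    return make_resolved(
        age=40, heart_rate=80, resp_rate=16, sbp=120, dbp=70, map=86.7,
        spo2=98, temp=37.0, gcs=15, wbc=8, bands_pct=0, platelets=250,
        bun=5, bun_unit="mmol/L", lactate=1.0,
        altered_mental_status=TriState.NO, confusion=TriState.NO,
        nursing_home_resident=TriState.NO,
        lower_respiratory_infection=TriState.NO,
        terminal_illness=TriState.NO, shock_after_fluids=TriState.NO,
        on_supplemental_o2=TriState.NO, organ_dysfunction=TriState.NO,
    )


def random_resolved(rng: np.random.Generator):
    """A random fully observed record with integer-valued vitals/labs.

    Integer values keep band-edge semantics identical between the package
    and the independently coded table oracle.
    """
    def tri():
        return TriState.YES if rng.random() < 0.5 else TriState.NO

    return make_resolved(
        id=f"r{rng.integers(1, 10**9)}",
        age=int(rng.integers(0, 101)),
        heart_rate=int(rng.integers(20, 251)),
        resp_rate=int(rng.integers(0, 81)),
        sbp=int(rng.integers(40, 201)),
        dbp=int(rng.integers(20, 121)),
        map=int(rng.integers(20, 201)),
        spo2=int(rng.integers(50, 101)),
        temp=float(rng.uniform(34, 42)),
        gcs=int(rng.integers(3, 16)),
        wbc=float(rng.uniform(0.5, 40)),
        bands_pct=int(rng.integers(0, 61)),
        platelets=int(rng.integers(10, 501)),
        bun=int(rng.integers(1, 41)),
        bun_unit="mmol/L",
        lactate=float(rng.uniform(0.3, 15)),
        altered_mental_status=tri(),
        confusion=tri(),
        nursing_home_resident=tri(),
        lower_respiratory_infection=tri(),
        terminal_illness=tri(),
        shock_after_fluids=tri(),
        on_supplemental_o2=tri(),
        organ_dysfunction=tri(),
        survived_to_discharge=bool(rng.random() < 0.5),
    )
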