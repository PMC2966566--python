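"""Patient data model, tabular I/O, and the normal-imputation convention.

Severity scores for emergency-department sepsis are computed from the
*first-recorded* ED vital signs, a handful of laboratory values, and
chart-abstracted history flags.  Chart abstraction leaves gaps, and the
convention used when these scores were originally derived is that any
variable not recorded in the chart is taken to be *normal or not present*.
:func:`resolve` makes that convention explicit and auditable: it is a total
function from a possibly-gappy :class:`PatientRecord` to a fully populated
:class:`ResolvedRecord`, and every filled-in field is flagged so downstream
consumers can distinguish observed physiology from the convention.

Blood urea nitrogen is the one field that arrives in two unit systems
(mmol/L or mg/dL); it is canonicalized to mmol/L using the 2.8 conversion
factor under which 19.6 mg/dL is exactly 7 mmol/L, the CURB-65 threshold.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TriState",
    "Sex",
    "PatientRecord",
    "ResolvedRecord",
    "NORMAL_SENTINELS",
    "BUN_MGDL_PER_MMOL",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "resolve",
    "mean_arterial_pressure",
]

#: mg/dL of blood urea nitrogen per mmol/L of urea.  Fixed at 2.8 so that the
#: CURB-65 threshold equivalence (7 mmol/L <-> 19.6 mg/dL) is exact.
BUN_MGDL_PER_MMOL = 2.8


class TriState(str, enum.Enum):
    """A chart finding that can be present, absent, or simply never recorded."""

    YES = "yes"
    NO = "no"
    UNRECORDED = "unrecorded"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP estimated from systolic and diastolic pressure: (SBP + 2*DBP)/3."""
    return (sbp + 2.0 * dbp) / 3.0


#: Normal sentinel values substituted for unrecorded vitals/labs.  Chosen so
#: that an imputed field contributes 0 points to every score implemented in
#: :mod:`sepscore.severity_scores` — the operational meaning of "abstracted
#: as normal".  All tri-state history flags resolve to "no"/not-present.
NORMAL_SENTINELS: dict[str, float] = {
    "age": 40.0,
    "heart_rate": 80.0,
    "resp_rate": 16.0,
    "sbp": 120.0,
    "dbp": 70.0,
    "spo2": 98.0,
    "temp": 37.0,
    "gcs": 15.0,
    "wbc": 8.0,
    "bands_pct": 0.0,
    "platelets": 250.0,
    "bun_mmol": 5.0,
    "lactate": 1.0,
}

_NUMERIC_FIELDS = (
    "age",
    "heart_rate",
    "resp_rate",
    "sbp",
    "dbp",
    "map",
    "spo2",
    "temp",
    "gcs",
    "wbc",
    "bands_pct",
    "platelets",
    "bun",
    "lactate",
)

_TRISTATE_FIELDS = (
    "altered_mental_status",
    "confusion",
    "nursing_home_resident",
    "lower_respiratory_infection",
    "terminal_illness",
    "shock_after_fluids",
    "on_supplemental_o2",
    "organ_dysfunction",
)

#: Canonical column order for delimited-text cohort files.
COLUMNS = (
    "id",
    "age",
    "sex",
    "heart_rate",
    "resp_rate",
    "sbp",
    "dbp",
    "map",
    "spo2",
    "temp",
    "gcs",
    "altered_mental_status",
    "confusion",
    "nursing_home_resident",
    "lower_respiratory_infection",
    "terminal_illness",
    "shock_after_fluids",
    "on_supplemental_o2",
    "wbc",
    "bands_pct",
    "platelets",
    "bun",
    "bun_unit",
    "lactate",
    "organ_dysfunction",
    "survived_to_discharge",
)


class CohortFormatError(ValueError):
    """A cohort file is missing a required column or is otherwise unusable."""


@dataclass
class PatientRecord:
    """One patient's raw observed variables, possibly with gaps.

    Numeric fields are ``None`` when not recorded; history flags are
    :attr:`TriState.UNRECORDED`.  ``bun`` carries an explicit unit tag —
    unitless urea values are rejected.
    """

    id: str
    age: Optional[float] = None
    sex: Sex = Sex.UNKNOWN
    heart_rate: Optional[float] = None   # beats/min
    resp_rate: Optional[float] = None    # breaths/min
    sbp: Optional[float] = None          # mmHg
    dbp: Optional[float] = None          # mmHg
    map: Optional[float] = None          # mmHg, derivable from sbp/dbp
    spo2: Optional[float] = None         # percent, 0-100
    temp: Optional[float] = None         # degrees C
    gcs: Optional[float] = None          # 3-15
    altered_mental_status: TriState = TriState.UNRECORDED
    confusion: TriState = TriState.UNRECORDED
    nursing_home_resident: TriState = TriState.UNRECORDED
    lower_respiratory_infection: TriState = TriState.UNRECORDED
    terminal_illness: TriState = TriState.UNRECORDED
    shock_after_fluids: TriState = TriState.UNRECORDED  # SBP<90 after IVF bolus
    on_supplemental_o2: TriState = TriState.UNRECORDED
    wbc: Optional[float] = None          # 10^3 cells/uL
    bands_pct: Optional[float] = None    # percent immature neutrophils
    platelets: Optional[float] = None    # 10^3 cells/mm^3
    bun: Optional[float] = None
    bun_unit: Optional[str] = None       # "mmol/L" or "mg/dL"
    lactate: Optional[float] = None      # mmol/L
    organ_dysfunction: TriState = TriState.UNRECORDED
    survived_to_discharge: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.spo2 is not None and not (0.0 <= self.spo2 <= 100.0):
            raise ValueError(f"spo2 must be in [0, 100], got {self.spo2}")
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise ValueError(f"gcs must be in [3, 15], got {self.gcs}")
        for name in ("age", "heart_rate", "resp_rate", "sbp", "dbp", "map"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.bun is not None:
            if self.bun_unit not in ("mmol/L", "mg/dL"):
                raise ValueError(
                    "bun requires an explicit unit tag 'mmol/L' or 'mg/dL', "
                    f"got {self.bun_unit!r}"
                )

    def bun_mmol(self) -> Optional[float]:
        """BUN in canonical mmol/L, or ``None`` when unrecorded."""
        if self.bun is None:
            return None
        if self.bun_unit == "mg/dL":
            # rounded so the printed equivalence 19.6 mg/dL <-> 7 mmol/L is
            # exact despite binary floating point (19.6/2.8 = 7 + 1 ulp)
            return round(self.bun / BUN_MGDL_PER_MMOL, 9)
        return self.bun


@dataclass
class ResolvedRecord:
    """A :class:`PatientRecord` after imputation: no gaps, full provenance.

    ``provenance`` maps each clinical field name to ``"observed"``,
    ``"imputed_normal"`` or ``"derived"``.  ``bun`` is canonical mmol/L.
    """

    id: str
    age: float
    sex: Sex
    heart_rate: float
    resp_rate: float
    sbp: float
    dbp: float
    map: float
    spo2: float
    temp: float
    gcs: float
    altered_mental_status: bool
    confusion: bool
    nursing_home_resident: bool
    lower_respiratory_infection: bool
    terminal_illness: bool
    shock_after_fluids: bool
    on_supplemental_o2: bool
    wbc: float
    bands_pct: float
    platelets: float
    bun: float  # mmol/L
    lactate: float
    organ_dysfunction: bool
    survived_to_discharge: Optional[bool]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_imputed(self) -> int:
        return sum(1 for v in self.provenance.values() if v == "imputed_normal")


def resolve(record: PatientRecord) -> ResolvedRecord:
    """Apply the normal-imputation convention, producing a gap-free record.

    Unrecorded tri-states become ``False`` (not present); missing vitals and
    labs take the :data:`NORMAL_SENTINELS` value; a missing MAP is derived as
    (SBP + 2*DBP)/3 when both pressures were observed, otherwise imputed from
    the pressure sentinels; BUN is canonicalized to mmol/L.  Total function:
    it never raises on clinical content, and observed values pass through
    unchanged apart from unit canonicalization.
    """
    prov: dict[str, str] = {}
    vals: dict[str, object] = {}

    for name in ("age", "heart_rate", "resp_rate", "sbp", "dbp", "spo2",
                 "temp", "gcs", "wbc", "bands_pct", "platelets", "lactate"):
        v = getattr(record, name)
        if v is None:
            vals[name] = NORMAL_SENTINELS[name]
            prov[name] = "imputed_normal"
        else:
            vals[name] = float(v)
            prov[name] = "observed"

    if record.map is not None:
        vals["map"] = float(record.map)
        prov["map"] = "observed"
    elif record.sbp is not None and record.dbp is not None:
        vals["map"] = mean_arterial_pressure(record.sbp, record.dbp)
        prov["map"] = "derived"
    else:
        vals["map"] = mean_arterial_pressure(
            NORMAL_SENTINELS["sbp"], NORMAL_SENTINELS["dbp"]
        )
        prov["map"] = "imputed_normal"

    bun = record.bun_mmol()
    if bun is None:
        vals["bun"] = NORMAL_SENTINELS["bun_mmol"]
        prov["bun"] = "imputed_normal"
    else:
        vals["bun"] = bun
        prov["bun"] = "observed"

    for name in _TRISTATE_FIELDS:
        t = getattr(record, name)
        if t is TriState.UNRECORDED:
            vals[name] = False
            prov[name] = "imputed_normal"
        else:
            vals[name] = t is TriState.YES
            prov[name] = "observed"

    return ResolvedRecord(
        id=record.id,
        sex=record.sex,
        survived_to_discharge=record.survived_to_discharge,
        provenance=prov,
        **vals,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Tabular I/O

_TRUE_TOKENS = {"yes", "y", "true", "1"}
_FALSE_TOKENS = {"no", "n", "false", "0"}


def _parse_float(cell: str, column: str, row_id: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        logger.warning(
            "unparseable value %r in column %r for patient %r; treated as missing",
            cell, column, row_id,
        )
        return None


def _parse_tristate(cell: str) -> TriState:
    token = cell.strip().lower()
    if token in _TRUE_TOKENS:
        return TriState.YES
    if token in _FALSE_TOKENS:
        return TriState.NO
    return TriState.UNRECORDED


def _parse_bool(cell: str) -> Optional[bool]:
    token = cell.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    return None


def read_cohort(
    source: Union[str, IO[str]],
    column_map: Optional[dict[str, str]] = None,
    delimiter: str = ",",
    require_outcome: bool = False,
) -> list[PatientRecord]:
    """Read a delimited-text cohort file into :class:`PatientRecord` objects.

    Parameters
    ----------
    source
        Path or open text stream.  Must carry a header row; unknown columns
        are ignored.
    column_map
        Mapping from canonical field name to the source file's column name,
        for adapting foreign CSV dialects.  Unmapped canonical fields use
        their own name.
    delimiter
        Field separator (comma default, tab selectable).
    require_outcome
        Evaluation mode: the ``id`` and ``survived_to_discharge`` columns
        become mandatory and their absence is a :class:`CohortFormatError`
        naming the column.
    """
    column_map = column_map or {}
    df = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)

    def col(canonical: str) -> Optional[str]:
        name = column_map.get(canonical, canonical)
        return name if name in df.columns else None

    if require_outcome:
        for canonical in ("id", "survived_to_discharge"):
            if col(canonical) is None:
                raise CohortFormatError(
                    f"evaluation mode requires column "
                    f"{column_map.get(canonical, canonical)!r} ({canonical})"
                )

    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        c = col("id")
        rid = row[c].strip() if c else f"row{i + 1}"
        kwargs: dict[str, object] = {"id": rid}

        for name in _NUMERIC_FIELDS:
            c = col(name)
            if c is not None:
                kwargs[name] = _parse_float(row[c], name, rid)
        for name in _TRISTATE_FIELDS:
            c = col(name)
            if c is not None:
                kwargs[name] = _parse_tristate(row[c])

        c = col("bun_unit")
        unit = row[c].strip() if c else ""
        if kwargs.get("bun") is not None:
            kwargs["bun_unit"] = unit if unit else "mmol/L"

        c = col("sex")
        if c is not None:
            token = row[c].strip().lower()
            kwargs["sex"] = Sex(token) if token in ("male", "female") else Sex.UNKNOWN

        c = col("survived_to_discharge")
        if c is not None:
            kwargs["survived_to_discharge"] = _parse_bool(row[c])

        records.append(PatientRecord(**kwargs))  # type: ignore[arg-type]
    return records


def _format_cell(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, TriState):
        return "" if value is TriState.UNRECORDED else value.value
    if isinstance(value, Sex):
        return "" if value is Sex.UNKNOWN else value.value
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def write_cohort(
    records: Iterable[PatientRecord],
    sink: Union[str, IO[str]],
    delimiter: str = ",",
) -> None:
    """Write records as delimited text; round-trips losslessly with
    :func:`read_cohort` for observed fields (missing fields stay empty cells).
    """
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        if isinstance(r, ResolvedRecord):
            # Imputed fields are a convention, not data: write them as empty.
            prov = d.pop("provenance")
            for name, flag in prov.items():
                if flag == "imputed_normal":
                    d[name] = None
            d["bun_unit"] = "mmol/L" if d.get("bun") is not None else None
        rows.append({c: _format_cell(d.get(c)) for c in COLUMNS})
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df.to_csv(sink, sep=delimiter, index=False)
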