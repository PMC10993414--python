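"""Tabular I/O and domain records for plate-level assay data.

The package works from three delimited-text tables:

* a **well table** with one row per well of a 384-well plate (raw red/green
  fluorescence of the membrane-potential dye, cell count, luciferase
  luminescence, plus treatment annotation),
* a **chemical table** describing the tested chemicals (hydrophobicity
  descriptor ``log_dlipw``, mitochondrial target class, maximum tested
  concentration),
* a **detection table** with analytically measured molar concentrations of
  chemicals in water samples, referenced to the original water (REF = 1).

Readers validate every row and raise with row-indexed diagnostics; writers
round-trip all fields at full precision. Output ordering is deterministic
(sorted by plate, well position, run) regardless of input row order.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TreatmentKind",
    "MieClass",
    "WellRecord",
    "ChemicalRecord",
    "DetectedConcentration",
    "TableDialect",
    "SchemaError",
    "TableValidationError",
    "parse_well_id",
    "read_well_table",
    "write_well_table",
    "read_chemical_table",
    "write_chemical_table",
    "read_detection_table",
    "write_detection_table",
]

_WELL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLUMNS = 24
PLATE_WELLS = len(PLATE_ROWS) * PLATE_COLUMNS  # 384


class SchemaError(ValueError):
    """A required column is missing or the header is malformed."""


class TableValidationError(ValueError):
    """One or more rows violate record invariants.

    The message lists every offending row with its (0-based, data-only)
    row index and the reason.
    """

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems)
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}")


class TreatmentKind(str, enum.Enum):
    CHEMICAL = "chemical"
    WATER_EXTRACT = "water_extract"
    SOLVENT_CONTROL = "solvent_control"
    POSITIVE_CONTROL = "positive_control"
    BLANK = "blank"

    @property
    def is_control(self) -> bool:
        return self in (
            TreatmentKind.SOLVENT_CONTROL,
            TreatmentKind.POSITIVE_CONTROL,
            TreatmentKind.BLANK,
        )


class MieClass(str, enum.Enum):
    """Molecular initiating event in mitochondria (or baseline/unknown)."""

    COMPLEX_I = "complexI"
    COMPLEX_II = "complexII"
    COMPLEX_III = "complexIII"
    COMPLEX_V = "complexV"
    UNCOUPLER = "uncoupler"
    MULTIPLE = "multiple"
    BASELINE = "baseline"
    UNKNOWN = "unknown"


def parse_well_id(well_id: str) -> tuple[str, int]:
    """Split a 384-well identifier like ``"B17"`` into ``("B", 17)``.

    Raises ``ValueError`` for anything outside rows A..P / columns 1..24.
    """
    m = _WELL_RE.match(well_id.strip())
    if not m:
        raise ValueError(f"malformed well id {well_id!r} (expected e.g. 'A1'..'P24')")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= PLATE_COLUMNS:
        raise ValueError(f"well column {col} outside 1..{PLATE_COLUMNS} in {well_id!r}")
    return row, col


@dataclass(frozen=True)
class WellRecord:
    """Raw multiplexed readouts of one well with treatment annotation.

    ``dose`` is a molar concentration for chemicals and a relative
    enrichment factor REF (L water per L bioassay) for water extracts;
    controls and blanks carry dose 0. ``red_signal``/``green_signal`` are
    the aggregate (560/624 nm) and monomer (475/536 nm) channels of the
    membrane-potential dye in arbitrary units.
    """

    plate_id: str
    well_id: str
    treatment_id: str
    treatment_kind: TreatmentKind
    dose: float
    dose_unit: str  # "M" for chemicals, "REF" for water extracts, "none" for controls
    red_signal: float
    green_signal: float
    cell_count: int
    luminescence: float
    run_id: str

    def __post_init__(self) -> None:
        parse_well_id(self.well_id)
        kind = TreatmentKind(self.treatment_kind)
        object.__setattr__(self, "treatment_kind", kind)
        for name in ("dose", "red_signal", "green_signal", "luminescence"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.cell_count < 0:
            raise ValueError(f"cell_count must be >= 0, got {self.cell_count}")
        if kind.is_control:
            if self.dose != 0:
                raise ValueError(f"control/blank well has nonzero dose {self.dose}")
        elif self.dose == 0:
            raise ValueError("treated well has dose 0 (doses must be positive)")
        if not kind.is_control and self.dose_unit not in ("M", "REF"):
            raise ValueError(f"dose_unit must be 'M' or 'REF' for treatments, got {self.dose_unit!r}")

    @property
    def well_position(self) -> tuple[int, int]:
        row, col = parse_well_id(self.well_id)
        return PLATE_ROWS.index(row), col


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and properties of one test chemical.

    ``log_dlipw`` is log10 of the liposome-water distribution ratio at
    pH 7.4 (L/kg lipid), the hydrophobicity descriptor driving baseline
    toxicity. May be ``None`` when no baseline prediction is wanted.
    """

    chem_id: str
    name: str = ""
    log_dlipw: float | None = None
    mie_class: MieClass = MieClass.UNKNOWN
    max_test_conc: float | None = None  # M

    def __post_init__(self) -> None:
        object.__setattr__(self, "mie_class", MieClass(self.mie_class))
        if self.log_dlipw is not None and not math.isfinite(self.log_dlipw):
            object.__setattr__(self, "log_dlipw", None)
        if self.max_test_conc is not None and self.max_test_conc <= 0:
            raise ValueError(f"max_test_conc must be positive, got {self.max_test_conc}")


@dataclass(frozen=True)
class DetectedConcentration:
    """Analytically detected concentration of one chemical in one sample.

    ``concentration`` is molar, expressed per litre of original water
    (REF = 1 basis); sample enrichment is applied upstream.
    """

    sample_id: str
    chem_id: str
    concentration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(f"concentration must be finite and >= 0, got {self.concentration}")


@dataclass(frozen=True)
class TableDialect:
    """Delimited-text dialect: default comma separator, period decimal."""

    delimiter: str = ","
    decimal: str = "."


_WELL_FIELDS = [f.name for f in fields(WellRecord)]
_NUMERIC_WELL_FIELDS = ("dose", "red_signal", "green_signal", "luminescence")


def _read_raw(path: str | Path, dialect: TableDialect, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (no header)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df

def _to_float(raw: str, column: str, decimal: str) -> float:
    s = raw.strip()
    if decimal != ".":
        s = s.replace(decimal, ".")
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"non-numeric value {raw!r} in column {column!r}") from None


def read_well_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[WellRecord]:
    """Read a well table, validating every row.

    Returns records sorted by (plate_id, row, column, run_id). Raises
    :class:`SchemaError` on a missing column and
    :class:`TableValidationError` listing every row that fails to parse
    or violates a :class:`WellRecord` invariant.
    """
    dialect = dialect or TableDialect()
    df = _read_raw(path, dialect, _WELL_FIELDS)
    records: list[WellRecord] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        try:
            kwargs = {
                "plate_id": raw["plate_id"].strip(),
                "well_id": raw["well_id"].strip(),
                "treatment_id": raw["treatment_id"].strip(),
                "treatment_kind": TreatmentKind(raw["treatment_kind"].strip()),
                "dose_unit": raw["dose_unit"].strip(),
                "run_id": raw["run_id"].strip(),
                "cell_count": int(round(_to_float(raw["cell_count"], "cell_count", dialect.decimal))),
            }
            for name in _NUMERIC_WELL_FIELDS:
                kwargs[name] = _to_float(raw[name], name, dialect.decimal)
            records.append(WellRecord(**kwargs))
        except ValueError as exc:
            problems.append((i, str(exc)))
    if problems:
        raise TableValidationError(problems)
    return sort_wells(records)


def sort_wells(records: Iterable[WellRecord]) -> list[WellRecord]:
    return sorted(records, key=lambda r: (r.plate_id, *r.well_position, r.run_id))


def write_well_table(
    records: Iterable[WellRecord], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write well records as delimited text (lossless round trip)."""
    dialect = dialect or TableDialect()
    rows = [
        {
            **{f: getattr(r, f) for f in _WELL_FIELDS},
            "treatment_kind": r.treatment_kind.value,
        }
        for r in sort_wells(records)
    ]
    df = pd.DataFrame(rows, columns=_WELL_FIELDS)
    df.to_csv(path, sep=dialect.delimiter, decimal=dialect.decimal, index=False)


def read_chemical_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[ChemicalRecord]:
    """Read a chemical property table.

    Unknown ``mie_class`` strings map to :attr:`MieClass.UNKNOWN` with a
    warning; duplicate ``chem_id`` rows raise.
    """
    dialect = dialect or TableDialect()
    df = _read_raw(path, dialect, ["chem_id", "log_dlipw", "mie_class"])
    records: list[ChemicalRecord] = []
    problems: list[tuple[int, str]] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        chem_id = raw["chem_id"].strip()
        if chem_id in seen:
            raise TableValidationError([(i, f"duplicate chem_id {chem_id!r}")])
        seen.add(chem_id)
        mie_raw = raw["mie_class"].strip()
        try:
            mie = MieClass(mie_raw)
        except ValueError:
            warnings.warn(
                f"unknown mie_class {mie_raw!r} for {chem_id!r}; recorded as 'unknown'",
                stacklevel=2,
            )
            mie = MieClass.UNKNOWN
        try:
            ldw_raw = raw["log_dlipw"].strip()
            log_dlipw = _to_float(ldw_raw, "log_dlipw", dialect.decimal) if ldw_raw else None
            mtc_raw = raw.get("max_test_conc", "").strip()
            max_test_conc = _to_float(mtc_raw, "max_test_conc", dialect.decimal) if mtc_raw else None
            records.append(
                ChemicalRecord(
                    chem_id=chem_id,
                    name=raw.get("name", "").strip(),
                    log_dlipw=log_dlipw,
                    mie_class=mie,
                    max_test_conc=max_test_conc,
                )
            )
        except ValueError as exc:
            problems.append((i, str(exc)))
    if problems:
        raise TableValidationError(problems)
    return sorted(records, key=lambda r: r.chem_id)


def write_chemical_table(
    records: Iterable[ChemicalRecord], path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    rows = [
        {
            "chem_id": r.chem_id,
            "name": r.name,
            "log_dlipw": r.log_dlipw if r.log_dlipw is not None else "",
            "mie_class": r.mie_class.value,
            "max_test_conc": r.max_test_conc if r.max_test_conc is not None else "",
        }
        for r in sorted(records, key=lambda r: r.chem_id)
    ]
    pd.DataFrame(rows, columns=["chem_id", "name", "log_dlipw", "mie_class", "max_test_conc"]).to_csv(
        path, sep=dialect.delimiter, decimal=dialect.decimal, index=False
    )


def read_detection_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[DetectedConcentration]:
    """Read detected molar concentrations per (sample, chemical).

    Duplicate (sample_id, chem_id) pairs raise.
    """
    dialect = dialect or TableDialect()
    df = _read_raw(path, dialect, ["sample_id", "chem_id", "concentration"])
    records: list[DetectedConcentration] = []
    problems: list[tuple[int, str]] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        key = (raw["sample_id"].strip(), raw["chem_id"].strip())
        if key in seen:
            problems.append((i, f"duplicate (sample_id, chem_id) {key!r}"))
            continue
        seen.add(key)
        try:
            records.append(
                DetectedConcentration(
                    sample_id=key[0],
                    chem_id=key[1],
                    concentration=_to_float(raw["concentration"], "concentration", dialect.decimal),
                )
            )
        except ValueError as exc:
            problems.append((i, str(exc)))
    if problems:
        raise TableValidationError(problems)
    return sorted(records, key=lambda r: (r.sample_id, r.chem_id))


def write_detection_table(
    records: Iterable[DetectedConcentration], path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    rows = [
        {"sample_id": r.sample_id, "chem_id": r.chem_id, "concentration": r.concentration}
        for r in sorted(records, key=lambda r: (r.sample_id, r.chem_id))
    ]
    pd.DataFrame(rows, columns=["sample_id", "chem_id", "concentration"]).to_csv(
        path, sep=dialect.delimiter, decimal=dialect.decimal, index=False
    )
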