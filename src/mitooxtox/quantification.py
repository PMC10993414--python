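"""Per-well effect quantification from raw plate signals.

Three endpoints are derived from the multiplexed readout, each normalized
to the solvent-control wells of the *same plate* (plate-internal
normalization absorbs plate-to-plate gain differences):

* **mmp** — loss of mitochondrial membrane potential from the red/green
  dye ratio: ``effect% = (1 - r / r_ctrl) * 100`` where ``r`` is the
  well's red/green ratio and ``r_ctrl`` the mean solvent-control ratio.
  0 at control level, 100 = complete loss of the red aggregate signal.
* **cytotoxicity** — reduction in cell number:
  ``effect% = (1 - N / N_ctrl) * 100``.
* **oxidative_stress** — luciferase induction ratio ``IR = L / L_ctrl``
  of the Nrf2/ARE reporter; 1 at control level.

All three are invariant under a common positive rescaling of the raw
signals across a plate (gain invariance), and by construction the mean
over a plate's solvent controls is exactly 0 (mmp, cytotoxicity) or 1
(induction ratio). Negative effects (stimulation) are retained.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .assay_io import TableDialect, TreatmentKind, WellRecord, sort_wells

__all__ = [
    "Endpoint",
    "EndpointMeasure",
    "mmp_effect",
    "cytotoxicity_effect",
    "induction_ratio",
    "quantify_all",
    "measures_to_frame",
    "write_measure_table",
]

MIN_CONTROL_WELLS = 3


class Endpoint(str, enum.Enum):
    MMP = "mmp"
    CYTOTOXICITY = "cytotoxicity"
    OXIDATIVE_STRESS = "oxidative_stress"


@dataclass(frozen=True)
class EndpointMeasure:
    """One well's normalized effect for one endpoint.

    ``value`` is a percent effect in (-inf, 100] for mmp/cytotoxicity and
    a nonnegative induction ratio for oxidative_stress. ``dose`` is molar
    for chemicals and REF for water extracts (0 for controls).
    """

    treatment_id: str
    dose: float
    endpoint: Endpoint
    value: float
    run_id: str


def _by_plate(records: Iterable[WellRecord]) -> dict[str, list[WellRecord]]:
    plates: dict[str, list[WellRecord]] = {}
    for r in sort_wells(records):
        plates.setdefault(r.plate_id, []).append(r)
    return plates


def _plate_effects(
    records: Iterable[WellRecord],
    endpoint: Endpoint,
    signal: Callable[[WellRecord], float | None],
    transform: Callable[[float, float], float],
) -> list[EndpointMeasure]:
    out: list[EndpointMeasure] = []
    for plate_id, wells in _by_plate(records).items():
        usable = []
        for w in wells:
            if w.treatment_kind is TreatmentKind.BLANK:
                continue
            s = signal(w)
            if s is None:
                warnings.warn(
                    f"well {plate_id}/{w.well_id}: unusable signal for {endpoint.value}; excluded",
                    stacklevel=3,
                )
                continue
            usable.append((w, s))
        ctrl = [s for w, s in usable if w.treatment_kind is TreatmentKind.SOLVENT_CONTROL]
        if len(ctrl) < MIN_CONTROL_WELLS:
            raise ValueError(
                f"plate {plate_id!r}: {len(ctrl)} usable solvent-control wells for "
                f"{endpoint.value}, need >= {MIN_CONTROL_WELLS}"
            )
        ctrl_mean = float(np.mean(ctrl))
        if ctrl_mean == 0:
            raise ValueError(f"plate {plate_id!r}: zero mean control signal for {endpoint.value}")
        out.extend(
            EndpointMeasure(w.treatment_id, w.dose, endpoint, transform(s, ctrl_mean), w.run_id)
            for w, s in usable
        )
    return out


def mmp_effect(records: Iterable[WellRecord]) -> list[EndpointMeasure]:
    """Percent loss of membrane potential from the red/green dye ratio.

    Wells with zero green (monomer) signal cannot form a ratio; they are
    excluded with a warning. Requires >= 3 usable solvent controls per
    plate.
    """
    return _plate_effects(
        records,
        Endpoint.MMP,
        lambda w: (w.red_signal / w.green_signal) if w.green_signal > 0 else None,
        lambda r, r0: (1.0 - r / r0) * 100.0,
    )


def cytotoxicity_effect(records: Iterable[WellRecord]) -> list[EndpointMeasure]:
    """Percent reduction in cell count relative to plate solvent controls."""
    return _plate_effects(
        records,
        Endpoint.CYTOTOXICITY,
        lambda w: float(w.cell_count),
        lambda n, n0: (1.0 - n / n0) * 100.0,
    )


def induction_ratio(records: Iterable[WellRecord]) -> list[EndpointMeasure]:
    """Luciferase induction ratio IR = L / mean solvent-control L."""
    return _plate_effects(
        records,
        Endpoint.OXIDATIVE_STRESS,
        lambda w: w.luminescence,
        lambda l, l0: l / l0,
    )


def quantify_all(records: Iterable[WellRecord]) -> list[EndpointMeasure]:
    """All three endpoints for a collection of wells (possibly many plates)."""
    records = list(records)
    return mmp_effect(records) + cytotoxicity_effect(records) + induction_ratio(records)


def measures_to_frame(measures: Sequence[EndpointMeasure]) -> pd.DataFrame:
    """Tidy frame: treatment_id, dose, endpoint, value, run_id."""
    return pd.DataFrame(
        [
            {
                "treatment_id": m.treatment_id,
                "dose": m.dose,
                "endpoint": m.endpoint.value,
                "value": m.value,
                "run_id": m.run_id,
            }
            for m in measures
        ],
        columns=["treatment_id", "dose", "endpoint", "value", "run_id"],
    )


def write_measure_table(
    measures: Sequence[EndpointMeasure], path: str | Path, dialect: TableDialect | None = None
) -> None:
    dialect = dialect or TableDialect()
    measures_to_frame(measures).to_csv(
        path, sep=dialect.delimiter, decimal=dialect.decimal, index=False
    )
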