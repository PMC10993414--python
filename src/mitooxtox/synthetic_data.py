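"""Synthetic plate-data generator with known ground truth.

Emulates the study design end to end so every downstream stage is
testable without instrument data: 384-well plates, an 11-point 1:2 serial
dilution per treatment dosed in duplicate wells, a 16-well solvent-control
column, and three independent experimental runs (one plate each). Seeding
density is 10,000 cells per well.

Expected signals per well at dose ``c``:

* green (dye monomer):    ``G0``
* red (dye aggregate):    ``G0 * ratio0 * (1 - f_mmp(c)/100)``
* cell count:             ``N0 * (1 - f_cyto(c)/100)``
* luminescence:           ``L0 * (1 + slope_ox * c)``

where ``f`` is the log-logistic truth per endpoint. Noise is multiplicative
lognormal (mean 1, coefficient of variation ``signal_cv``) on the three
optical signals and gamma-Poisson (negative-binomial) on counts; with
``signal_cv = 0`` and ``count_dispersion = None`` every well equals its
expectation and the pipeline must recover the generative parameters to
optimizer tolerance. All randomness flows from the explicit seed.

Mixtures are simulated under strict concentration addition: at relative
enrichment factor rho, the toxic units ``T(rho) = sum_i rho*C_i/ec50_i``
replace ``c/ec50`` in the shared-shape log-logistic, which requires the
constituents to share hill (and top) per endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay_io import (
    PLATE_COLUMNS,
    PLATE_ROWS,
    MieClass,
    ChemicalRecord,
    DetectedConcentration,
    TableDialect,
    TreatmentKind,
    WellRecord,
)

__all__ = [
    "EndpointTruth",
    "GenerativeChemical",
    "NoiseModel",
    "PlateDesign",
    "simulate_plate",
    "simulate_screen",
    "simulate_mixture_sample",
    "dilution_series",
    "default_top_conc",
    "chemical_records",
    "write_truth_table",
]

CONTROL_COLUMN = PLATE_COLUMNS  # column 24 reserved for solvent controls
SOLVENT_CONTROLS_PER_PLATE = len(PLATE_ROWS)  # 16
TREATMENT_WELLS_PER_PLATE = len(PLATE_ROWS) * (PLATE_COLUMNS - 1)  # 368


@dataclass(frozen=True)
class EndpointTruth:
    """True log-logistic parameters of one percent-effect endpoint."""

    top: float  # %
    ec50: float  # M (or REF for pre-scaled mixtures)
    hill: float

    def __post_init__(self) -> None:
        if not 0 < self.top <= 100:
            raise ValueError(f"top must be in (0, 100], got {self.top}")
        if not self.ec50 > 0 or not self.hill > 0:
            raise ValueError("ec50 and hill must be positive")

    def effect(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore"):
            return np.where(c > 0, self.top / (1.0 + (self.ec50 / np.maximum(c, 1e-300)) ** self.hill), 0.0)

    def ec_at(self, level: float) -> float:
        if level >= self.top:
            raise ValueError(f"level {level} not reached (top {self.top})")
        return self.ec50 * (level / (self.top - level)) ** (1.0 / self.hill)


@dataclass(frozen=True)
class GenerativeChemical:
    """Ground-truth effect profile of one simulated chemical.

    ``mmp``/``cytotoxicity`` are log-logistic truths (``None`` = inert on
    that endpoint); ``ox_slope`` is the linear induction-ratio slope in IR
    units per M (0 = no oxidative-stress response).
    """

    chem_id: str
    mmp: EndpointTruth | None
    cytotoxicity: EndpointTruth | None
    ox_slope: float = 0.0
    log_dlipw: float | None = None
    mie_class: MieClass = MieClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.ox_slope < 0:
            raise ValueError("ox_slope must be >= 0")
        object.__setattr__(self, "mie_class", MieClass(self.mie_class))


@dataclass(frozen=True)
class NoiseModel:
    """Per-well noise: lognormal CV on signals, gamma-Poisson counts.

    ``count_dispersion`` is the negative-binomial size parameter theta
    (variance = mu + mu^2/theta); ``None`` disables count noise entirely.
    ``signal_cv = 0`` disables signal noise. Defaults reflect ~5% CV.
    """

    signal_cv: float = 0.05
    count_dispersion: float | None = 400.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_cv < 0:
            raise ValueError("signal_cv must be >= 0")
        if self.count_dispersion is not None and self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive or None")


@dataclass(frozen=True)
class PlateDesign:
    """Dosing design and expected control-level signals.

    ``n_conc`` doses per treatment in a geometric 1:`dilution_factor`
    ladder from the per-treatment top concentration, ``n_tech_rep``
    duplicate wells, ``n_runs`` independent repetitions (one plate each).
    """

    n_conc: int = 11
    n_tech_rep: int = 2
    n_runs: int = 3
    dilution_factor: float = 2.0
    g0: float = 1000.0  # control green signal
    ratio0: float = 2.0  # control red/green ratio
    l0: float = 500.0  # control luminescence
    n0: int = 10_000  # seeded cells per well

    def __post_init__(self) -> None:
        if self.n_conc < 1 or self.n_tech_rep < 1 or self.n_runs < 1:
            raise ValueError("design counts must be >= 1")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")

    @property
    def wells_per_treatment(self) -> int:
        return self.n_conc * self.n_tech_rep


def dilution_series(top_conc: float, n_conc: int = 11, dilution_factor: float = 2.0) -> np.ndarray:
    """Strictly decreasing geometric dose ladder from ``top_conc``."""
    if top_conc <= 0:
        raise ValueError("top_conc must be positive")
    return top_conc / dilution_factor ** np.arange(n_conc, dtype=float)


def default_top_conc(chem: GenerativeChemical, span: float = 10.0**1.5) -> float:
    """Top test concentration bracketing the chemical's potency.

    Centres the 3-decade default ladder on the geometric mean of the
    active-endpoint EC50s, i.e. top = span * gmean(ec50), so both curve
    midpoints are tested when they lie within ~3 decades of each other.
    """
    ec50s = [t.ec50 for t in (chem.mmp, chem.cytotoxicity) if t is not None]
    if not ec50s:
        raise ValueError(f"{chem.chem_id}: inert on both fitted endpoints; give top_conc explicitly")
    return span * float(np.exp(np.mean(np.log(ec50s))))


def _well_ids() -> list[str]:
    ids = []
    for col in range(1, PLATE_COLUMNS):  # columns 1..23 for treatments
        for row in PLATE_ROWS:
            ids.append(f"{row}{col}")
    return ids


def _noisy_signal(rng: np.random.Generator, expected: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return expected
    sigma = math.sqrt(math.log1p(cv * cv))
    factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=expected.shape)
    return expected * factors


def _noisy_count(rng: np.random.Generator, expected: np.ndarray, theta: float | None) -> np.ndarray:
    if theta is None:
        return np.round(expected).astype(int)
    lam = expected * rng.gamma(shape=theta, scale=1.0 / theta, size=expected.shape)
    return rng.poisson(lam)


@dataclass(frozen=True)
class _WellExpectation:
    treatment_id: str
    treatment_kind: TreatmentKind
    dose: float
    dose_unit: str
    f_mmp: float
    f_cyto: float
    ir: float


def _emit_plate(
    expectations: Sequence[_WellExpectation],
    plate_id: str,
    run_id: str,
    design: PlateDesign,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> list[WellRecord]:
    treatment_ids = _well_ids()
    if len(expectations) > len(treatment_ids):
        raise ValueError(
            f"design overflow: {len(expectations)} treatment wells > "
            f"{len(treatment_ids)} available (384-well plate, control column reserved)"
        )
    n = len(expectations)
    f_mmp = np.array([e.f_mmp for e in expectations])
    f_cyto = np.array([e.f_cyto for e in expectations])
    ir = np.array([e.ir for e in expectations])
    nc = SOLVENT_CONTROLS_PER_PLATE
    exp_green = np.full(n + nc, design.g0)
    exp_red = design.g0 * design.ratio0 * np.concatenate([(1.0 - f_mmp / 100.0), np.ones(nc)])
    exp_count = design.n0 * np.concatenate([(1.0 - f_cyto / 100.0), np.ones(nc)])
    exp_lum = design.l0 * np.concatenate([ir, np.ones(nc)])
    green = _noisy_signal(rng, exp_green, noise.signal_cv)
    red = _noisy_signal(rng, np.maximum(exp_red, 0.0), noise.signal_cv)
    lum = _noisy_signal(rng, np.maximum(exp_lum, 0.0), noise.signal_cv)
    count = _noisy_count(rng, np.clip(exp_count, 0.0, None), noise.count_dispersion)
    records = []
    for i, e in enumerate(expectations):
        records.append(
            WellRecord(
                plate_id=plate_id,
                well_id=treatment_ids[i],
                treatment_id=e.treatment_id,
                treatment_kind=e.treatment_kind,
                dose=e.dose,
                dose_unit=e.dose_unit,
                red_signal=float(red[i]),
                green_signal=float(green[i]),
                cell_count=int(count[i]),
                luminescence=float(lum[i]),
                run_id=run_id,
            )
        )
    for j in range(nc):
        records.append(
            WellRecord(
                plate_id=plate_id,
                well_id=f"{PLATE_ROWS[j]}{CONTROL_COLUMN}",
                treatment_id="solvent",
                treatment_kind=TreatmentKind.SOLVENT_CONTROL,
                dose=0.0,
                dose_unit="none",
                red_signal=float(red[n + j]),
                green_signal=float(green[n + j]),
                cell_count=int(count[n + j]),
                luminescence=float(lum[n + j]),
                run_id=run_id,
            )
        )
    return records


def _chemical_expectations(
    chems: Sequence[GenerativeChemical],
    design: PlateDesign,
    top_conc: dict[str, float] | None,
) -> list[_WellExpectation]:
    expectations = []
    for chem in chems:
        top = (top_conc or {}).get(chem.chem_id) or default_top_conc(chem)
        doses = dilution_series(top, design.n_conc, design.dilution_factor)
        for c in doses:
            f_m = float(chem.mmp.effect(c)) if chem.mmp else 0.0
            f_c = float(chem.cytotoxicity.effect(c)) if chem.cytotoxicity else 0.0
            for _ in range(design.n_tech_rep):
                expectations.append(
                    _WellExpectation(
                        treatment_id=chem.chem_id,
                        treatment_kind=TreatmentKind.CHEMICAL,
                        dose=float(c),
                        dose_unit="M",
                        f_mmp=f_m,
                        f_cyto=f_c,
                        ir=1.0 + chem.ox_slope * float(c),
                    )
                )
    return expectations


def simulate_plate(
    chems: Sequence[GenerativeChemical],
    design: PlateDesign | None = None,
    noise: NoiseModel | None = None,
    *,
    top_conc: dict[str, float] | None = None,
    plate_prefix: str = "P1",
) -> list[WellRecord]:
    """Simulate one plate layout over ``design.n_runs`` independent runs.

    Each run is an independently noised plate (plate id
    ``{plate_prefix}-run{k}``, run id ``run{k}``) with its own 16 solvent
    controls. Raises on design overflow (more treatment wells than the
    384-well layout holds). Fully reproducible from ``noise.seed``.
    """
    design = design or PlateDesign()
    noise = noise or NoiseModel()
    expectations = _chemical_expectations(chems, design, top_conc)
    rng = np.random.default_rng(noise.seed)
    records: list[WellRecord] = []
    for k in range(1, design.n_runs + 1):
        records.extend(
            _emit_plate(expectations, f"{plate_prefix}-run{k}", f"run{k}", design, noise, rng)
        )
    return records


def simulate_screen(
    chems: Sequence[GenerativeChemical],
    design: PlateDesign | None = None,
    noise: NoiseModel | None = None,
    *,
    top_conc: dict[str, float] | None = None,
) -> list[WellRecord]:
    """Simulate an arbitrary-size screen, chunking chemicals over plates."""
    design = design or PlateDesign()
    noise = noise or NoiseModel()
    capacity = TREATMENT_WELLS_PER_PLATE // design.wells_per_treatment
    if capacity < 1:
        raise ValueError("one treatment does not fit on a plate")
    records: list[WellRecord] = []
    rng = np.random.default_rng(noise.seed)
    for p, start in enumerate(range(0, len(chems), capacity), start=1):
        batch = chems[start : start + capacity]
        expectations = _chemical_expectations(batch, design, top_conc)
        for k in range(1, design.n_runs + 1):
            records.extend(
                _emit_plate(expectations, f"P{p}-run{k}", f"run{k}", design, noise, rng)
            )
    return records


def _common_shape(
    truths: Sequence[EndpointTruth], approximate: bool, what: str
) -> tuple[float, float]:
    """Shared (top, hill) of mixture constituents; weighted mean if approximate."""
    tops = np.array([t.top for t in truths])
    hills = np.array([t.hill for t in truths])
    if not approximate:
        if np.ptp(hills) > 1e-9 * hills.mean() or np.ptp(tops) > 1e-9 * tops.mean():
            raise ValueError(
                f"mixture constituents differ in {what} shape (top/hill); "
                "concentration addition with a shared curve requires equal shapes "
                "(pass approximate=True to use mean shape)"
            )
    return float(tops.mean()), float(hills.mean())


def simulate_mixture_sample(
    constituents: Sequence[tuple[GenerativeChemical, float]],
    design: PlateDesign | None = None,
    noise: NoiseModel | None = None,
    *,
    sample_id: str = "S1",
    top_ref: float = 100.0,
    withhold: Sequence[str] = (),
    approximate: bool = False,
) -> tuple[list[WellRecord], list[DetectedConcentration]]:
    """Simulate a water-extract dilution series plus its detection table.

    ``constituents`` pairs each chemical with its concentration ``C_i``
    in mol per litre of original water. Wells are dosed on the REF scale
    (top REF 100 by default). Per endpoint the mixture follows strict
    concentration addition: toxic units ``T(rho) = sum_i rho*C_i/ec50_i``
    and effect ``top / (1 + T^-hill)`` with the constituents' common top
    and hill. The returned detection table omits chemicals named in
    ``withhold`` (simulating unidentified constituents).
    """
    design = design or PlateDesign()
    noise = noise or NoiseModel()
    if not constituents:
        raise ValueError("empty mixture")
    refs = dilution_series(top_ref, design.n_conc, design.dilution_factor)

    def mixture_effect(endpoint: str) -> np.ndarray:
        truths = []
        tu_per_ref = 0.0
        for chem, ci in constituents:
            t: EndpointTruth | None = getattr(chem, endpoint)
            if t is not None and ci > 0:
                truths.append(t)
                tu_per_ref += ci / t.ec50
        if not truths:
            return np.zeros_like(refs)
        top, hill = _common_shape(truths, approximate, endpoint)
        tu = refs * tu_per_ref
        return np.where(tu > 0, top / (1.0 + tu ** (-hill)), 0.0)

    f_mmp = mixture_effect("mmp")
    f_cyto = mixture_effect("cytotoxicity")
    slope_per_ref = sum(chem.ox_slope * ci for chem, ci in constituents)
    expectations = []
    for i, rho in enumerate(refs):
        for _ in range(design.n_tech_rep):
            expectations.append(
                _WellExpectation(
                    treatment_id=sample_id,
                    treatment_kind=TreatmentKind.WATER_EXTRACT,
                    dose=float(rho),
                    dose_unit="REF",
                    f_mmp=float(f_mmp[i]),
                    f_cyto=float(f_cyto[i]),
                    ir=1.0 + slope_per_ref * float(rho),
                )
            )
    rng = np.random.default_rng(noise.seed)
    records: list[WellRecord] = []
    for k in range(1, design.n_runs + 1):
        records.extend(
            _emit_plate(expectations, f"{sample_id}-run{k}", f"run{k}", design, noise, rng)
        )
    detections = [
        DetectedConcentration(sample_id=sample_id, chem_id=chem.chem_id, concentration=float(ci))
        for chem, ci in constituents
        if chem.chem_id not in set(withhold)
    ]
    return records, sorted(detections, key=lambda d: d.chem_id)


def chemical_records(chems: Iterable[GenerativeChemical]) -> list[ChemicalRecord]:
    """Chemical property table matching the generative set."""
    return [
        ChemicalRecord(
            chem_id=c.chem_id,
            name=c.chem_id,
            log_dlipw=c.log_dlipw,
            mie_class=c.mie_class,
        )
        for c in chems
    ]


def write_truth_table(
    chems: Iterable[GenerativeChemical], path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Ground-truth parameter table for test harnesses."""
    dialect = dialect or TableDialect()
    rows = []
    for c in chems:
        rows.append(
            {
                "chem_id": c.chem_id,
                "mmp_top": c.mmp.top if c.mmp else "",
                "mmp_ec50": c.mmp.ec50 if c.mmp else "",
                "mmp_hill": c.mmp.hill if c.mmp else "",
                "cyto_top": c.cytotoxicity.top if c.cytotoxicity else "",
                "cyto_ec50": c.cytotoxicity.ec50 if c.cytotoxicity else "",
                "cyto_hill": c.cytotoxicity.hill if c.cytotoxicity else "",
                "ox_slope": c.ox_slope,
                "log_dlipw": c.log_dlipw if c.log_dlipw is not None else "",
                "mie_class": c.mie_class.value,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, decimal=dialect.decimal, index=False)
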