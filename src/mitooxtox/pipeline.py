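"""End-to-end orchestration: raw well tables -> effect tables -> fits ->
specificity / BEQ accounting, with a YAML-configurable entry point used by
the command-line interface.

Two workflows mirror the two kinds of screens:

* :func:`run_chemical_screen` — single chemicals dosed in molar units;
  produces per-well effects, per-chemical fits (IC10, EC10 with the
  10x-IC10 secondary-effect rule, EC_IR1.5 with the IC10 mask), the
  baseline-toxicity prediction, TR/SR ratios and a classification, plus a
  scatter export of SR_baseline vs SR_cytotoxicity.
* :func:`run_water_screen` — water extracts dosed on the REF scale;
  produces per-sample fits (SR_cytotoxicity as the unitless IC10/EC10
  ratio), BEQ_bio/BEQ_chem iceberg accounting against a reference
  chemical and per-chemical contributions.

Every run writes a JSON manifest with the package version, config hash
and seed; rerunning with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .assay_io import (
    ChemicalRecord,
    DetectedConcentration,
    TableDialect,
    WellRecord,
    read_chemical_table,
    read_detection_table,
    read_well_table,
)
from .crc import (
    DEFAULT_EFFECT_LEVEL,
    DEFAULT_IR_THRESHOLD,
    DEFAULT_MMP_CUTOFF_MULTIPLIER,
    FitResult,
    derive_ec10_mmp,
    fit_ecir15,
    fit_loglogistic,
)
from .iceberg import IcebergResult, evaluate_sample, iceberg_table, rep
from .quantification import (
    Endpoint,
    EndpointMeasure,
    measures_to_frame,
    quantify_all,
)
from .specificity import (
    DEFAULT_SPECIFICITY_THRESHOLD,
    BaselineModel,
    SpecificityResult,
    evaluate_chemical,
    predict_baseline_ic10,
    specificity_table,
)

__all__ = [
    "RunConfig",
    "evaluate_screen",
    "fits_to_frame",
    "run_chemical_screen",
    "run_water_screen",
]


@dataclass
class RunConfig:
    """Configuration for a pipeline run (YAML-loadable).

    Baseline QSAR coefficients have no defaults: they are cell-line
    specific and must be supplied when specificity analysis is requested.
    """

    well_table: str | None = None
    chemical_table: str | None = None
    detection_table: str | None = None
    rep_table: str | None = None  # water screen: chem_id,ec10 of single chemicals
    baseline_slope: float | None = None
    baseline_intercept: float | None = None
    specificity_threshold: float = DEFAULT_SPECIFICITY_THRESHOLD
    mmp_cutoff_multiplier: float = DEFAULT_MMP_CUTOFF_MULTIPLIER
    ir_threshold: float = DEFAULT_IR_THRESHOLD
    effect_level: float = DEFAULT_EFFECT_LEVEL
    reference_chem: str = "24DNP"
    outdir: str = "mitooxtox_out"
    plots: bool = False  # also write PNG figures (SR scatter / BEQ bars)
    seed: int = 0
    delimiter: str = ","
    decimal: str = "."

    def __post_init__(self) -> None:
        for name in ("specificity_threshold", "mmp_cutoff_multiplier", "ir_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.effect_level < 50:
            raise ValueError(f"effect_level must be in (0, 50), got {self.effect_level}")

    @property
    def dialect(self) -> TableDialect:
        return TableDialect(self.delimiter, self.decimal)

    @property
    def baseline_model(self) -> BaselineModel | None:
        if self.baseline_slope is None or self.baseline_intercept is None:
            return None
        return BaselineModel(self.baseline_slope, self.baseline_intercept)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def evaluate_screen(
    measures: Sequence[EndpointMeasure],
    *,
    effect_level: float = DEFAULT_EFFECT_LEVEL,
    ir_threshold: float = DEFAULT_IR_THRESHOLD,
    mmp_cutoff_multiplier: float = DEFAULT_MMP_CUTOFF_MULTIPLIER,
) -> dict[str, dict[Endpoint, FitResult]]:
    """Fit every treatment/endpoint with the masking chain applied.

    Per treatment: cytotoxicity is fitted first (IC10), the MMP fit is
    subjected to the 10x-IC10 secondary-effect rule, and the
    oxidative-stress linear fit masks doses above IC10. Solvent controls
    are skipped (their measures only anchor the normalization).
    """
    grouped: dict[str, dict[Endpoint, list[EndpointMeasure]]] = {}
    for m in measures:
        if m.dose > 0:
            grouped.setdefault(m.treatment_id, {}).setdefault(m.endpoint, []).append(m)
    out: dict[str, dict[Endpoint, FitResult]] = {}
    for treatment_id in sorted(grouped):
        by_ep = grouped[treatment_id]
        fits: dict[Endpoint, FitResult] = {}
        ic10 = None
        if Endpoint.CYTOTOXICITY in by_ep:
            fit_cyto = fit_loglogistic(by_ep[Endpoint.CYTOTOXICITY], effect_level=effect_level)
            fits[Endpoint.CYTOTOXICITY] = fit_cyto
            ic10 = fit_cyto.effect_conc
        if Endpoint.MMP in by_ep:
            fit_mmp = fit_loglogistic(by_ep[Endpoint.MMP], effect_level=effect_level)
            fits[Endpoint.MMP] = derive_ec10_mmp(fit_mmp, ic10, multiplier=mmp_cutoff_multiplier)
        if Endpoint.OXIDATIVE_STRESS in by_ep:
            fits[Endpoint.OXIDATIVE_STRESS] = fit_ecir15(
                by_ep[Endpoint.OXIDATIVE_STRESS], ic10, ir_threshold=ir_threshold
            )
        out[treatment_id] = fits
    return out


def fits_to_frame(fits: Mapping[str, Mapping[Endpoint, FitResult]]) -> pd.DataFrame:
    rows = []
    for treatment_id in sorted(fits):
        for endpoint in (Endpoint.CYTOTOXICITY, Endpoint.MMP, Endpoint.OXIDATIVE_STRESS):
            f = fits[treatment_id].get(endpoint)
            if f is None:
                continue
            p = f.params
            rows.append(
                {
                    "treatment_id": f.treatment_id,
                    "endpoint": f.endpoint.value,
                    "model": f.model,
                    "top": getattr(p, "top", None),
                    "ec50": getattr(p, "ec50", None),
                    "hill": getattr(p, "hill", None),
                    "slope": getattr(p, "slope", None),
                    "effect_conc": f.effect_conc,
                    "active": f.active,
                    "reason": f.reason or "",
                    "masked_doses": ";".join(f"{d:.6g}" for d in f.mask_info.excluded_doses),
                    "n_points": f.n_points,
                    "runs_used": f.runs_used,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["treatment_id", "endpoint", "model", "top", "ec50", "hill", "slope",
                 "effect_conc", "active", "reason", "masked_doses", "n_points", "runs_used"],
    )


def _write_manifest(cfg: RunConfig, outdir: Path, extra: Mapping[str, Any]) -> None:
    cfg_dict = asdict(cfg)
    manifest = {
        "package": "mitooxtox",
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _specificity_from_fits(
    fits: Mapping[str, Mapping[Endpoint, FitResult]],
    chemicals: Mapping[str, ChemicalRecord],
    model: BaselineModel | None,
    threshold: float,
) -> list[SpecificityResult]:
    results = []
    for chem_id in sorted(fits):
        by_ep = fits[chem_id]
        ic10 = by_ep.get(Endpoint.CYTOTOXICITY).effect_conc if Endpoint.CYTOTOXICITY in by_ep else None
        ec10 = by_ep.get(Endpoint.MMP).effect_conc if Endpoint.MMP in by_ep else None
        baseline = None
        if model is not None and chem_id in chemicals:
            baseline = predict_baseline_ic10(chemicals[chem_id], model)
        results.append(evaluate_chemical(chem_id, ic10, ec10, baseline, threshold))
    return results


def run_chemical_screen(
    cfg: RunConfig,
    *,
    wells: Sequence[WellRecord] | None = None,
    chemicals: Sequence[ChemicalRecord] | None = None,
    write: bool = True,
) -> dict[str, Any]:
    """Chemical screen: quantify, fit, and rank specificity.

    Inputs are read from ``cfg`` paths unless given in memory. Returns a
    dict with the measure/fit/specificity frames and the fit objects;
    with ``write=True`` also writes effects.csv, fits.csv,
    specificity.csv (the SR scatter data) and manifest.json to
    ``cfg.outdir``.
    """
    if wells is None:
        if cfg.well_table is None:
            raise ValueError("config: well_table path is required")
        wells = read_well_table(cfg.well_table, cfg.dialect)
    if not wells:
        raise ValueError("well table is empty")
    if chemicals is None:
        chemicals = (
            read_chemical_table(cfg.chemical_table, cfg.dialect) if cfg.chemical_table else []
        )
    if cfg.baseline_model is None and any(c.log_dlipw is not None for c in chemicals):
        raise ValueError(
            "config: baseline_slope/baseline_intercept are required for specificity "
            "analysis with log_dlipw-bearing chemicals"
        )
    chem_map = {c.chem_id: c for c in chemicals}
    measures = quantify_all(wells)
    fits = evaluate_screen(
        measures,
        effect_level=cfg.effect_level,
        ir_threshold=cfg.ir_threshold,
        mmp_cutoff_multiplier=cfg.mmp_cutoff_multiplier,
    )
    spec_results = _specificity_from_fits(
        fits, chem_map, cfg.baseline_model, cfg.specificity_threshold
    )
    out = {
        "measures": measures_to_frame(measures),
        "fits": fits,
        "fit_table": fits_to_frame(fits),
        "specificity": spec_results,
        "specificity_table": specificity_table(spec_results),
    }
    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out["measures"].to_csv(outdir / "effects.csv", index=False)
        out["fit_table"].to_csv(outdir / "fits.csv", index=False)
        out["specificity_table"].to_csv(outdir / "specificity.csv", index=False)
        if cfg.plots:
            from .plotting import plot_specificity_scatter

            plot_specificity_scatter(
                out["specificity_table"], outdir / "specificity_scatter.png",
                threshold=cfg.specificity_threshold,
            )
        _write_manifest(cfg, outdir, {"workflow": "chemicals", "n_wells": len(wells)})
    return out


def _read_rep_table(path: str | Path, dialect: TableDialect, reference_chem: str) -> tuple[dict[str, float], float]:
    """Read per-chemical EC10s (chem_id, ec10 in M) and derive REPs."""
    df = pd.read_csv(path, sep=dialect.delimiter, decimal=dialect.decimal)
    for col in ("chem_id", "ec10"):
        if col not in df.columns:
            raise ValueError(f"rep table {path}: missing column {col!r}")
    ec10s = {}
    for _, row in df.iterrows():
        val = row["ec10"]
        ec10s[str(row["chem_id"])] = None if pd.isna(val) else float(val)
    ref_ec10 = ec10s.get(reference_chem)
    if ref_ec10 is None:
        raise ValueError(f"rep table {path}: no EC10 for reference chemical {reference_chem!r}")
    reps = {c: (rep(ref_ec10, e) if e is not None else None) for c, e in ec10s.items()}
    return reps, ref_ec10


def run_water_screen(
    cfg: RunConfig,
    *,
    wells: Sequence[WellRecord] | None = None,
    detections: Sequence[DetectedConcentration] | None = None,
    reps: Mapping[str, float | None] | None = None,
    ec10_ref: float | None = None,
    write: bool = True,
) -> dict[str, Any]:
    """Water-extract screen: per-sample fits plus BEQ iceberg accounting.

    Needs the sample well table (REF doses), the detection table, and a
    REP source: either in-memory ``reps``/``ec10_ref`` or ``cfg.rep_table``
    (a CSV of single-chemical EC10s including the reference chemical).
    Detections of chemicals without a REP are warned about and reported
    as uncovered.
    """
    if wells is None:
        if cfg.well_table is None:
            raise ValueError("config: well_table path is required")
        wells = read_well_table(cfg.well_table, cfg.dialect)
    if not wells:
        raise ValueError("well table is empty")
    if detections is None:
        detections = (
            read_detection_table(cfg.detection_table, cfg.dialect) if cfg.detection_table else []
        )
    if reps is None or ec10_ref is None:
        if cfg.rep_table is None:
            raise ValueError("config: rep_table (or in-memory reps + ec10_ref) is required")
        reps, ec10_ref = _read_rep_table(cfg.rep_table, cfg.dialect, cfg.reference_chem)
    measures = quantify_all(wells)
    fits = evaluate_screen(
        measures,
        effect_level=cfg.effect_level,
        ir_threshold=cfg.ir_threshold,
        mmp_cutoff_multiplier=cfg.mmp_cutoff_multiplier,
    )
    sample_rows = []
    iceberg_results: list[IcebergResult] = []
    for sample_id in sorted(fits):
        by_ep = fits[sample_id]
        ic10 = by_ep.get(Endpoint.CYTOTOXICITY).effect_conc if Endpoint.CYTOTOXICITY in by_ep else None
        ec10 = by_ep.get(Endpoint.MMP).effect_conc if Endpoint.MMP in by_ep else None
        ecir = by_ep.get(Endpoint.OXIDATIVE_STRESS).effect_conc if Endpoint.OXIDATIVE_STRESS in by_ep else None
        sr_cyto = (ic10 / ec10) if (ic10 is not None and ec10 is not None) else None
        result = evaluate_sample(sample_id, ec10, detections, reps, ec10_ref)
        if result.uncovered:
            warnings.warn(
                f"sample {sample_id}: detected chemical(s) without REP "
                f"({', '.join(result.uncovered)}); contributing zero",
                stacklevel=2,
            )
        iceberg_results.append(result)
        sample_rows.append(
            {
                "sample_id": sample_id, "ic10_ref": ic10, "ec10_ref_scale": ec10,
                "ec_ir_ref": ecir, "sr_cyto": sr_cyto,
            }
        )
    out = {
        "measures": measures_to_frame(measures),
        "fits": fits,
        "fit_table": fits_to_frame(fits),
        "samples": pd.DataFrame(
            sample_rows,
            columns=["sample_id", "ic10_ref", "ec10_ref_scale", "ec_ir_ref", "sr_cyto"],
        ),
        "iceberg": iceberg_results,
        "iceberg_table": iceberg_table(iceberg_results),
    }
    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out["measures"].to_csv(outdir / "effects.csv", index=False)
        out["fit_table"].to_csv(outdir / "fits.csv", index=False)
        out["samples"].to_csv(outdir / "samples.csv", index=False)
        out["iceberg_table"].to_csv(outdir / "iceberg.csv", index=False)
        if cfg.plots:
            from .plotting import plot_contributions

            plot_contributions(iceberg_results, outdir / "beq_contributions.png")
        _write_manifest(
            cfg, outdir,
            {"workflow": "water", "n_wells": len(wells), "n_detections": len(detections)},
        )
    return out
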