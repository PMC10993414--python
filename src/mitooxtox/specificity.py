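"""Baseline-toxicity prediction, toxic ratio, and specificity ratios.

Every chemical exerts at least *baseline toxicity* — nonspecific membrane
disturbance driven by hydrophobicity. A one-descriptor QSAR predicts the
nominal concentration causing 10% baseline cytotoxicity from the
liposome-water distribution ratio at pH 7.4:

    log10(1 / IC10_baseline [M]) = slope * log10(D_lipw) + intercept

The coefficients are cell-line specific and are supplied as configuration
(:class:`BaselineModel`), not hard-coded.

Three ratios locate a chemical relative to that floor:

* ``TR  = IC10_baseline / IC10``      — excess cytotoxicity over baseline,
* ``SR_cytotoxicity = IC10 / EC10_mmp`` — MMP specificity vs. cell death,
* ``SR_baseline = IC10_baseline / EC10_mmp`` — MMP potency vs. baseline,

with the algebraic identity ``SR_baseline = TR * SR_cytotoxicity``. A
ratio above 10 (strict, configurable) flags a specific mode of action;
chemicals with all available ratios <= 10 behave like baseline toxicants.
All ratios are dimensionless and invariant under a common rescaling of
concentration units.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .assay_io import ChemicalRecord

__all__ = [
    "BaselineModel",
    "Classification",
    "SpecificityResult",
    "predict_baseline_ic10",
    "toxic_ratio",
    "specificity_ratios",
    "classify",
    "specificity_table",
    "DEFAULT_SPECIFICITY_THRESHOLD",
]

DEFAULT_SPECIFICITY_THRESHOLD = 10.0


@dataclass(frozen=True)
class BaselineModel:
    """Coefficients of the baseline-toxicity QSAR (cell-line specific)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"baseline QSAR slope must be positive, got {self.slope}")


class Classification(str, enum.Enum):
    BASELINE_LIKE = "baseline_like"
    SPECIFIC_CYTOTOXIC = "specific_cytotoxic"
    SPECIFIC_MMP = "specific_mmp"
    SPECIFIC_BOTH = "specific_both"
    INACTIVE = "inactive"


@dataclass(frozen=True)
class SpecificityResult:
    chem_id: str
    ic10: float | None  # measured, M
    ec10_mmp: float | None  # measured, M
    ic10_baseline: float | None  # predicted, M
    tr: float | None
    sr_cyto: float | None
    sr_baseline: float | None
    classification: Classification


def predict_baseline_ic10(
    chem: ChemicalRecord | float | None, model: BaselineModel
) -> float | None:
    """Predicted molar IC10 from baseline toxicity, or None without log_dlipw."""
    log_dlipw = chem.log_dlipw if isinstance(chem, ChemicalRecord) else chem
    if log_dlipw is None:
        name = chem.chem_id if isinstance(chem, ChemicalRecord) else "<value>"
        warnings.warn(f"no log_dlipw for {name}; baseline IC10 not predicted", stacklevel=2)
        return None
    return 10.0 ** (-(model.slope * log_dlipw + model.intercept))


def toxic_ratio(ic10_baseline: float | None, ic10: float | None) -> float | None:
    """TR = predicted baseline IC10 over measured IC10 (absent if either is)."""
    if ic10_baseline is None or ic10 is None:
        return None
    if ic10 <= 0 or ic10_baseline <= 0:
        raise ValueError("concentrations must be positive")
    return ic10_baseline / ic10


def specificity_ratios(
    ic10: float | None, ec10_mmp: float, ic10_baseline: float | None
) -> tuple[float | None, float | None]:
    """(SR_cytotoxicity, SR_baseline) for a measured MMP effect concentration."""
    if not ec10_mmp > 0:
        raise ValueError(f"ec10_mmp must be positive, got {ec10_mmp}")
    sr_cyto = None if ic10 is None else ic10 / ec10_mmp
    sr_baseline = None if ic10_baseline is None else ic10_baseline / ec10_mmp
    return sr_cyto, sr_baseline


def classify(
    tr: float | None,
    sr_cyto: float | None,
    sr_baseline: float | None,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> Classification:
    """Classify a chemical from its available ratios (strict > threshold).

    Exactly the threshold does not count as specific. With no ratio
    derivable the chemical is ``inactive``.
    """
    if tr is None and sr_cyto is None and sr_baseline is None:
        return Classification.INACTIVE
    cyto_specific = tr is not None and tr > threshold
    mmp_specific = (sr_cyto is not None and sr_cyto > threshold) or (
        sr_baseline is not None and sr_baseline > threshold
    )
    if cyto_specific and mmp_specific:
        return Classification.SPECIFIC_BOTH
    if cyto_specific:
        return Classification.SPECIFIC_CYTOTOXIC
    if mmp_specific:
        return Classification.SPECIFIC_MMP
    return Classification.BASELINE_LIKE


def evaluate_chemical(
    chem_id: str,
    ic10: float | None,
    ec10_mmp: float | None,
    ic10_baseline: float | None,
    threshold: float = DEFAULT_SPECIFICITY_THRESHOLD,
) -> SpecificityResult:
    """Assemble all ratios and the classification for one chemical."""
    tr = toxic_ratio(ic10_baseline, ic10)
    if ec10_mmp is not None:
        sr_cyto, sr_baseline = specificity_ratios(ic10, ec10_mmp, ic10_baseline)
    else:
        sr_cyto = sr_baseline = None
    return SpecificityResult(
        chem_id=chem_id,
        ic10=ic10,
        ec10_mmp=ec10_mmp,
        ic10_baseline=ic10_baseline,
        tr=tr,
        sr_cyto=sr_cyto,
        sr_baseline=sr_baseline,
        classification=classify(tr, sr_cyto, sr_baseline, threshold),
    )


def specificity_table(results: Sequence[SpecificityResult]) -> pd.DataFrame:
    """Tidy export, one row per chemical (also the Fig-1B-style scatter data)."""
    return pd.DataFrame(
        [
            {
                "chem_id": r.chem_id,
                "ic10": r.ic10,
                "ec10_mmp": r.ec10_mmp,
                "ic10_baseline": r.ic10_baseline,
                "tr": r.tr,
                "sr_cyto": r.sr_cyto,
                "sr_baseline": r.sr_baseline,
                "classification": r.classification.value,
            }
            for r in results
        ],
        columns=[
            "chem_id", "ic10", "ec10_mmp", "ic10_baseline",
            "tr", "sr_cyto", "sr_baseline", "classification",
        ],
    )
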