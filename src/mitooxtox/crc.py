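"""Concentration-response curve fitting and effect-concentration derivation.

The percent-effect endpoints (cytotoxicity, MMP loss) are fitted with a
four-parameter log-logistic model

    effect(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill)

with ``bottom`` fixed at 0 by default: effects are defined relative to
plate solvent controls, so the zero-dose asymptote is 0 by construction.
Fitting is bounded least squares on the log10-dose axis with a
deterministic multi-start over a grid of initial ec50 values spanning the
tested range. Effect concentrations at a given absolute level (IC10 for
cytotoxicity, EC10 for MMP) come from the closed-form inversion

    c(level) = ec50 * ((level - bottom) / (top - level))^(1 / hill).

The oxidative-stress endpoint uses a linear induction-ratio model with the
intercept forced to 1 (a solvent control has IR 1 by definition):
``IR(c) = 1 + slope * c``, giving ``EC_IR1.5 = 0.5 / slope``.

Two masking rules guard against cytotoxicity artefacts:

* reporter-gene doses above the cytotoxicity IC10 are excluded before the
  EC_IR1.5 fit (cytotoxicity burst);
* an MMP EC10 more than 10x above the IC10 is suppressed as a secondary
  consequence of cell death (boundary inclusive: exactly 10x is retained).

A fit is called *active* only when the fitted top reaches the effect level
(default 10%) and the derived effect concentration lies within
[lowest tested dose / 10, highest tested dose] — no far extrapolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .quantification import Endpoint, EndpointMeasure

__all__ = [
    "LogLogistic4",
    "LinearIR",
    "MaskInfo",
    "FitResult",
    "loglogistic",
    "fit_loglogistic",
    "effect_conc_at",
    "fit_ecir15",
    "derive_ec10_mmp",
]

DEFAULT_EFFECT_LEVEL = 10.0  # percent
DEFAULT_IR_THRESHOLD = 1.5
DEFAULT_MMP_CUTOFF_MULTIPLIER = 10.0
_EC_RANGE_LOWER_MARGIN = 10.0  # effect conc may undershoot lowest dose by this factor
_N_STARTS = 5


@dataclass(frozen=True)
class LogLogistic4:
    bottom: float
    top: float
    ec50: float
    hill: float

    def __call__(self, c):
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / c) ** self.hill)


@dataclass(frozen=True)
class LinearIR:
    slope: float  # IR units per unit dose

    def __call__(self, c):
        return 1.0 + self.slope * np.asarray(c, dtype=float)


@dataclass(frozen=True)
class MaskInfo:
    excluded_doses: tuple[float, ...] = ()
    reason: str | None = None


@dataclass(frozen=True)
class FitResult:
    """Fitted model, derived effect concentration, and activity call."""

    treatment_id: str
    endpoint: Endpoint
    model: str  # "loglogistic4" | "linear_low_effect"
    params: LogLogistic4 | LinearIR | None
    effect_conc: float | None
    active: bool
    reason: str | None
    mask_info: MaskInfo
    n_points: int
    runs_used: int
    rss: float | None = None


def loglogistic(c, bottom: float, top: float, ec50: float, hill: float):
    """Forward four-parameter log-logistic curve."""
    return LogLogistic4(bottom, top, ec50, hill)(c)


def _dose_response_arrays(data: Sequence[EndpointMeasure]) -> tuple[np.ndarray, np.ndarray, int]:
    doses = np.array([m.dose for m in data if m.dose > 0], dtype=float)
    values = np.array([m.value for m in data if m.dose > 0], dtype=float)
    runs = len({m.run_id for m in data if m.dose > 0})
    return doses, values, runs


def fit_loglogistic(
    data: Sequence[EndpointMeasure],
    *,
    fix_bottom: bool = True,
    effect_level: float = DEFAULT_EFFECT_LEVEL,
) -> FitResult:
    """Fit the log-logistic model to pooled measurements of one treatment/endpoint.

    Measurements at dose 0 (controls) are excluded; the bottom asymptote
    of 0 already encodes the control level. Deterministic given the data:
    bounded least squares from ``_N_STARTS`` initial ec50 values spread
    over the tested dose range, keeping the lowest-cost solution.

    Raises ``ValueError`` when fewer distinct positive doses than free
    parameters are available.
    """
    data = list(data)
    if not data:
        raise ValueError("no measurements supplied")
    treatment_id = data[0].treatment_id
    endpoint = data[0].endpoint
    doses, values, runs = _dose_response_arrays(data)
    n_params = 3 if fix_bottom else 4
    distinct = np.unique(doses)
    if distinct.size < n_params:
        raise ValueError(
            f"{treatment_id}/{endpoint.value}: {distinct.size} distinct doses < {n_params} parameters"
        )
    x = np.log10(doses)
    lo, hi = float(x.min()), float(x.max())

    def residuals(theta):
        top, le, hill = theta[:3]
        bottom = 0.0 if fix_bottom else theta[3]
        with np.errstate(over="ignore"):
            pred = bottom + (top - bottom) / (1.0 + 10.0 ** (np.clip(hill * (le - x), -300, 300)))
        return pred - values

    top0 = float(np.clip(values.max(), 5.0, 100.0))
    bounds_lo = [1e-3, lo - 3.0, 0.05] + ([] if fix_bottom else [-50.0])
    bounds_hi = [100.0, hi + 3.0, 20.0] + ([] if fix_bottom else [50.0])
    best = None
    for le0 in np.linspace(lo, hi, _N_STARTS):
        theta0 = [top0, float(le0), 1.0] + ([] if fix_bottom else [0.0])
        theta0 = np.clip(theta0, bounds_lo, bounds_hi)
        try:
            sol = least_squares(residuals, theta0, bounds=(bounds_lo, bounds_hi), method="trf")
        except Exception:  # numerical failure from one start is not fatal
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return FitResult(
            treatment_id, endpoint, "loglogistic4", None, None, False,
            "fit did not converge", MaskInfo(), doses.size, runs,
        )
    top, le, hill = best.x[:3]
    bottom = 0.0 if fix_bottom else float(best.x[3])
    params = LogLogistic4(bottom, float(top), float(10.0 ** le), float(hill))
    rss = float(2.0 * best.cost)
    return _finalize_loglogistic(
        treatment_id, endpoint, params, doses, runs, rss, effect_level
    )


def _finalize_loglogistic(
    treatment_id: str,
    endpoint: Endpoint,
    params: LogLogistic4,
    doses: np.ndarray,
    runs: int,
    rss: float,
    effect_level: float,
) -> FitResult:
    base = dict(
        treatment_id=treatment_id, endpoint=endpoint, model="loglogistic4",
        params=params, mask_info=MaskInfo(), n_points=int(doses.size),
        runs_used=runs, rss=rss,
    )
    if params.top < effect_level:
        return FitResult(
            **base, effect_conc=None, active=False,
            reason=f"fitted top {params.top:.3g}% below effect level {effect_level:g}%",
        )
    ec = effect_conc_at(params, effect_level)
    lo_ok = ec >= doses.min() / _EC_RANGE_LOWER_MARGIN
    hi_ok = ec <= doses.max()
    if not (lo_ok and hi_ok):
        return FitResult(
            **base, effect_conc=None, active=False,
            reason=f"effect concentration {ec:.3g} outside tested range",
        )
    return FitResult(**base, effect_conc=float(ec), active=True, reason=None)


def effect_conc_at(fit: FitResult | LogLogistic4, level: float) -> float:
    """Closed-form dose at which the fitted curve crosses ``level`` percent.

    Strictly increasing in ``level``. Raises ``ValueError`` when the level
    is not reached within the model (top <= level) or not above the bottom.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if not isinstance(params, LogLogistic4):
        raise TypeError("effect_conc_at requires a fitted log-logistic model")
    if level <= params.bottom:
        raise ValueError(f"level {level} not above curve bottom {params.bottom}")
    if params.top <= level:
        raise ValueError(f"level {level} not reached: fitted top is {params.top}")
    return params.ec50 * ((level - params.bottom) / (params.top - level)) ** (1.0 / params.hill)


def fit_ecir15(
    data: Sequence[EndpointMeasure],
    ic10: float | None = None,
    *,
    ir_threshold: float = DEFAULT_IR_THRESHOLD,
) -> FitResult:
    """Linear induction-ratio fit with cytotoxicity masking.

    Doses strictly above the cytotoxicity ``ic10`` are excluded first
    (reporter signal above that is confounded by the cytotoxicity burst).
    The retained points are fitted with ``IR = 1 + slope * c`` through the
    forced intercept 1, and ``EC_IR = (ir_threshold - 1) / slope``. The
    result is inactive when fewer than 3 distinct doses survive masking
    ("over-masked"), when the slope is not positive, or when the derived
    concentration exceeds the highest retained dose.
    """
    data = list(data)
    if not data:
        raise ValueError("no measurements supplied")
    treatment_id = data[0].treatment_id
    doses, values, runs = _dose_response_arrays(data)
    if doses.size == 0:
        raise ValueError(f"{treatment_id}: no positive-dose induction-ratio data")
    if ic10 is not None:
        keep = doses <= ic10
        mask = MaskInfo(
            excluded_doses=tuple(sorted(set(doses[~keep]))),
            reason="above cytotoxicity IC10" if (~keep).any() else None,
        )
    else:
        keep = np.ones_like(doses, dtype=bool)
        mask = MaskInfo()
    kept_doses, kept_values = doses[keep], values[keep]
    base = dict(
        treatment_id=treatment_id, endpoint=Endpoint.OXIDATIVE_STRESS,
        model="linear_low_effect", mask_info=mask, n_points=int(kept_doses.size),
        runs_used=runs,
    )
    if np.unique(kept_doses).size < 3:
        return FitResult(**base, params=None, effect_conc=None, active=False, reason="over-masked")
    # least squares through the forced intercept (IR - 1 = slope * c)
    slope = float(np.sum(kept_doses * (kept_values - 1.0)) / np.sum(kept_doses**2))
    resid = (1.0 + slope * kept_doses) - kept_values
    base["rss"] = float(np.sum(resid**2))
    params = LinearIR(slope)
    if slope <= 0:
        return FitResult(
            **base, params=params, effect_conc=None, active=False, reason="non-positive slope"
        )
    ec = (ir_threshold - 1.0) / slope
    if ec > kept_doses.max():
        return FitResult(
            **base, params=params, effect_conc=None, active=False,
            reason=f"EC_IR{ir_threshold:g} beyond highest retained dose",
        )
    return FitResult(**base, params=params, effect_conc=float(ec), active=True, reason=None)


def derive_ec10_mmp(
    fit_mmp: FitResult,
    ic10: float | None,
    *,
    multiplier: float = DEFAULT_MMP_CUTOFF_MULTIPLIER,
) -> FitResult:
    """Apply the relaxed cytotoxicity cutoff to an MMP fit.

    When the MMP effect concentration exceeds ``multiplier`` x IC10
    (strictly — the boundary is inclusive on the retained side), the MMP
    response is judged a secondary effect of cytotoxicity and no EC10 is
    reported. With no IC10 (non-cytotoxic chemical) the fit passes through
    unchanged.
    """
    if ic10 is None or fit_mmp.effect_conc is None or not fit_mmp.active:
        return fit_mmp
    if fit_mmp.effect_conc > multiplier * ic10:
        return replace(
            fit_mmp,
            effect_conc=None,
            active=False,
            reason="secondary to cytotoxicity",
        )
    return fit_mmp
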