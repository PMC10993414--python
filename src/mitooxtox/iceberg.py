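"""Iceberg (BEQ) mixture accounting for water-sample effects.

A water extract's measured effect is the tip of an iceberg of mostly
unidentified constituents. Two bioanalytical equivalent concentrations
(BEQs), both expressed in mol of a reference chemical (default the
uncoupler 2,4-dinitrophenol, 24DNP) per litre of original water, make the
measured and chemically explained effects comparable:

* ``BEQ_bio = EC10_ref / EC10_sample`` — from the sample's fitted effect
  concentration in REF units (L water / L bioassay), capturing the whole
  mixture;
* ``BEQ_chem = sum_i REP_i * C_i`` — from detected concentrations ``C_i``
  (mol / L water) weighted by relative effect potencies
  ``REP_i = EC10_ref / EC10_i``.

``pct_explained = 100 * BEQ_chem / BEQ_bio`` quantifies how much of the
measured mixture effect the detected chemicals account for, assuming
concentration addition (valid for constituents sharing the mode of
action). Chemicals detected but without a REP (inactive on MMP, e.g. a
chemical with no measurable effect up to its solubility limit) contribute
zero and are reported in ``uncovered`` rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assay_io import DetectedConcentration

__all__ = [
    "IcebergResult",
    "rep",
    "beq_bio",
    "beq_chem",
    "pct_explained",
    "evaluate_sample",
    "iceberg_table",
]


@dataclass(frozen=True)
class IcebergResult:
    """BEQ accounting for one water sample.

    ``contributions`` maps each covered detected chemical to its fraction
    of BEQ_chem (fractions sum to 1 when BEQ_chem > 0); ``uncovered``
    lists detected chemicals lacking a REP.
    """

    sample_id: str
    beq_bio: float | None  # mol ref-equivalents / L water
    beq_chem: float  # same units; 0 when nothing detected/covered
    pct_explained: float | None  # percent, None when beq_bio is absent
    contributions: dict[str, float]
    beq_i: dict[str, float]
    uncovered: tuple[str, ...]


def rep(ec10_ref: float, ec10_i: float) -> float:
    """Relative effect potency of chemical i vs. the reference: EC10_ref / EC10_i."""
    if not (ec10_ref > 0 and ec10_i > 0):
        raise ValueError("effect concentrations must be positive")
    return ec10_ref / ec10_i


def beq_bio(ec10_ref: float, ec10_sample: float) -> float:
    """Measured mixture effect as reference-equivalents per litre of water.

    ``ec10_ref`` is molar; ``ec10_sample`` is in REF units, so the ratio
    has units mol / L water.
    """
    if not (ec10_ref > 0 and ec10_sample > 0):
        raise ValueError("effect concentrations must be positive")
    return ec10_ref / ec10_sample


def beq_chem(
    detected: Iterable[DetectedConcentration],
    reps: Mapping[str, float],
) -> tuple[float, dict[str, float], dict[str, float], tuple[str, ...]]:
    """Sum detected concentrations weighted by REP.

    Returns ``(beq_chem, contributions, beq_i, uncovered)``. Chemicals
    absent from ``reps`` (or mapped to None) land in ``uncovered`` with
    zero contribution.
    """
    beq_i: dict[str, float] = {}
    uncovered: list[str] = []
    for d in detected:
        r = reps.get(d.chem_id)
        if r is None:
            uncovered.append(d.chem_id)
        else:
            beq_i[d.chem_id] = beq_i.get(d.chem_id, 0.0) + r * d.concentration
    total = sum(beq_i.values())
    contributions = {c: (v / total if total > 0 else 0.0) for c, v in beq_i.items()}
    return total, contributions, beq_i, tuple(sorted(uncovered))


def pct_explained(beq_chem_value: float, beq_bio_value: float | None) -> float | None:
    """Percent of the measured mixture effect explained by detected chemicals."""
    if beq_bio_value is None:
        return None
    if not beq_bio_value > 0:
        raise ValueError(f"beq_bio must be positive, got {beq_bio_value}")
    return 100.0 * beq_chem_value / beq_bio_value


def evaluate_sample(
    sample_id: str,
    ec10_sample_ref: float | None,
    detected: Iterable[DetectedConcentration],
    reps: Mapping[str, float],
    ec10_ref: float,
) -> IcebergResult:
    """Full BEQ accounting for one sample (inactive sample: BEQ_bio absent)."""
    detected = [d for d in detected if d.sample_id == sample_id]
    bio = None if ec10_sample_ref is None else beq_bio(ec10_ref, ec10_sample_ref)
    chem, contributions, beq_i, uncovered = beq_chem(detected, reps)
    return IcebergResult(
        sample_id=sample_id,
        beq_bio=bio,
        beq_chem=chem,
        pct_explained=pct_explained(chem, bio),
        contributions=contributions,
        beq_i=beq_i,
        uncovered=uncovered,
    )


def iceberg_table(results: Sequence[IcebergResult]) -> pd.DataFrame:
    """Long-format export mirroring a stacked-bar accounting.

    One ``total`` row per sample followed by one row per detected
    chemical with its BEQ_i and contribution (uncovered chemicals appear
    with zero values).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id, "row_kind": "total", "chem_id": "",
                "beq_bio": r.beq_bio, "beq_chem": r.beq_chem,
                "pct_explained": r.pct_explained, "beq_i": None, "contribution": None,
            }
        )
        for chem_id in sorted(r.beq_i):
            rows.append(
                {
                    "sample_id": r.sample_id, "row_kind": "chemical", "chem_id": chem_id,
                    "beq_bio": None, "beq_chem": None, "pct_explained": None,
                    "beq_i": r.beq_i[chem_id], "contribution": r.contributions[chem_id],
                }
            )
        for chem_id in r.uncovered:
            rows.append(
                {
                    "sample_id": r.sample_id, "row_kind": "uncovered", "chem_id": chem_id,
                    "beq_bio": None, "beq_chem": None, "pct_explained": None,
                    "beq_i": 0.0, "contribution": 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "row_kind", "chem_id", "beq_bio", "beq_chem",
                 "pct_explained", "beq_i", "contribution"],
    )
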