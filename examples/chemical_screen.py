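"""Run the full single-chemical screen: simulate a small panel spanning
mitochondrial target classes, fit all endpoints, and classify each
chemical by its toxic ratio (TR) and specificity ratios (SR).

TR = IC10,baseline / IC10 flags cytotoxicity in excess of the
hydrophobicity-driven baseline; SR_cytotoxicity = IC10 / EC10(MMP) and
SR_baseline = IC10,baseline / EC10(MMP) flag specific action on the
membrane potential. Ratios above 10 count as specific.
"""

import numpy as np

from mitooxtox import (
    EndpointTruth,
    GenerativeChemical,
    NoiseModel,
    PlateDesign,
    RunConfig,
    run_chemical_screen,
    simulate_screen,
)
from mitooxtox.synthetic_data import chemical_records

# Arbitrary illustrative baseline-QSAR coefficients; for real analyses use
# coefficients fitted for your cell line (they are required configuration).
QSAR_SLOPE, QSAR_INTERCEPT = 0.9, 1.0


def baseline_chem(cid, ldw):
    """IC10 equal to the QSAR prediction, MMP tracking cytotoxicity."""
    ic10 = 10.0 ** (-(QSAR_SLOPE * ldw + QSAR_INTERCEPT))
    ec50 = ic10 * 8.0  # top 90, hill 1 -> IC10 = ec50/8
    return GenerativeChemical(
        cid, mmp=EndpointTruth(90.0, ec50, 1.0),
        cytotoxicity=EndpointTruth(90.0, ec50, 1.0), log_dlipw=ldw, mie_class="baseline",
    )


def complex1_chem(cid, ec50_mmp, ec50_cyto):
    """MMP far more potent than cytotoxicity; TR ~ 1 by construction."""
    ic10 = ec50_cyto * (10.0 / 80.0) ** (1 / 1.5)
    ldw = (-np.log10(ic10) - QSAR_INTERCEPT) / QSAR_SLOPE
    return GenerativeChemical(
        cid, mmp=EndpointTruth(95.0, ec50_mmp, 1.5),
        cytotoxicity=EndpointTruth(90.0, ec50_cyto, 1.5),
        log_dlipw=float(ldw), mie_class="complexI",
    )


chems = [
    baseline_chem("solventY", 1.5),
    baseline_chem("phenolZ", 2.5),
    complex1_chem("inhibitorA", 1e-7, 1e-5),
    complex1_chem("inhibitorB", 3e-8, 4e-6),
    GenerativeChemical(  # uncoupler-like: strong excess cytotoxicity
        "uncouplerC", mmp=EndpointTruth(95.0, 4e-6, 1.5),
        cytotoxicity=EndpointTruth(90.0, 8e-6, 1.5), log_dlipw=1.0, mie_class="uncoupler",
    ),
]

wells = simulate_screen(chems, PlateDesign(), NoiseModel(signal_cv=0.05, seed=7))
cfg = RunConfig(
    baseline_slope=QSAR_SLOPE, baseline_intercept=QSAR_INTERCEPT, outdir="scratch_screen_out"
)
out = run_chemical_screen(cfg, wells=wells, chemicals=chemical_records(chems), write=False)

cols = ["chem_id", "ic10", "ec10_mmp", "tr", "sr_cyto", "sr_baseline", "classification"]
print(out["specificity_table"][cols].to_string(index=False, float_format="{:.3g}".format))

# Expected pattern: the baseline chemicals have TR and SRs near 1
# (baseline_like); the complex-I-like inhibitors show SR >> 10 with TR ~ 1
# (specific_mmp); the uncoupler shows TR >> 10 (specific cytotoxicity,
# here with SR_baseline also > 10 -> specific_both).
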