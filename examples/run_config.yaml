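# Example run configuration for `mitooxtox chemicals` / `mitooxtox water`.
# Paths are relative to where you invoke the CLI.

well_table: data/wells.csv          # raw per-well table (see README for columns)
chemical_table: data/chemicals.csv  # chem_id, name, log_dlipw, mie_class[, max_test_conc]
# detection_table: data/detections.csv   # water screen: sample_id, chem_id, concentration (M)
# rep_table: data/reps.csv               # water screen: chem_id, ec10 (M), incl. the reference

# Baseline-toxicity QSAR, log10(1/IC10_baseline [M]) = slope*logD_lipw + intercept.
# The coefficients are cell-line specific and MUST be supplied by the user
# from a prediction model fitted for their cell line (e.g. the published
# AREc32 model of Lee et al. 2021); the values below are illustrative only.
baseline_slope: 0.9
baseline_intercept: 1.0

specificity_threshold: 10   # TR/SR above this count as specific (strict)
mmp_cutoff_multiplier: 10   # EC10_mmp > 10*IC10 -> secondary to cytotoxicity
ir_threshold: 1.5           # induction ratio defining EC_IR1.5
effect_level: 10            # percent effect for IC10/EC10
reference_chem: 24DNP       # BEQ reference chemical id (water screen)

outdir: mitooxtox_out
plots: false                # true -> also write PNG figures
seed: 0
delimiter: ","
decimal: "."
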