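# Methods

This note documents the models, conventions, and design choices behind
`mitooxtox`. It is the package's own account of its science; every number
quoted here is computed by the test suite, the examples, or
`scripts/acceptance.py`.

## Assay model

The package evaluates a multiplexed 384-well assay that reads three
endpoints from the same plate of AREc32 reporter cells after 24 h of
exposure:

* **MMP loss** — a membrane-potential dye partitions into polarized
  mitochondria as red-fluorescent aggregates (560/624 nm) and remains in
  the cytosol as green monomer (475/536 nm). The per-well red/green ratio
  `r` falls as the membrane potential collapses. The percent effect is

  `effect% = (1 − r / r̄_ctrl) × 100`,

  where `r̄_ctrl` is the mean ratio over the solvent-control wells of the
  *same plate*. 0 = control level, 100 = complete loss of aggregate
  signal. The exact algebraic form of the published ratio normalization
  is rendered only graphically in the source literature; this
  ratio-of-ratios percent-effect form is the standard convention for
  ratiometric MMP dyes and is adopted as this package's definition.
* **Cytotoxicity** — percent reduction of the per-well cell count
  relative to the plate's solvent-control mean.
* **Oxidative stress** — the luciferase induction ratio
  `IR = L / L̄_ctrl` of the Nrf2/ARE reporter; 1 at control level.

Controls are per plate, never global: the normalization is plate-internal
by construction, which absorbs plate-to-plate gain differences and makes
all three measures exactly invariant under any uniform positive rescaling
of raw signals on a plate (verified by property tests). At least three
usable solvent-control wells per plate are required; wells with zero
green signal cannot form a ratio and are excluded with a warning.
Negative effects (stimulation/hormesis) are retained, not clipped.
Technical replicates stay as separate per-well measures; averaging
happens only inside curve fitting, preserving the replicate variance.

## Concentration–response models

Percent-effect endpoints are fitted with the four-parameter log-logistic
model

`effect(c) = bottom + (top − bottom) / (1 + (ec50/c)^hill)`,

with `bottom` fixed at 0 (effects are control-normalized, so the
zero-dose asymptote is 0 by construction), `top ∈ (0, 100]`, `hill ∈
[0.05, 20]`. Fitting is bounded least squares (`scipy.optimize.
least_squares`, trust-region reflective) on the log10-dose axis,
multi-started from five initial ec50 values spanning the tested range and
keeping the lowest-cost solution — deterministic given the data. Dose-0
(control) measurements are excluded from the fit; the fixed bottom
encodes them. Measurements from all independent runs are pooled into a
single fit per treatment and endpoint; per-run fits remain possible by
filtering the measures by `run_id`.

Effect concentrations at an absolute level (default 10%: IC10 for
cytotoxicity, EC10 for MMP) use the closed-form inversion
`c = ec50·((level − bottom)/(top − level))^(1/hill)`, which agrees with
numerical root finding on the forward curve to better than 1e−9 relative
(tested over 1000 random parameter sets) and is strictly increasing in
the level.

**Activity calls.** A treatment is active only when (i) the fitted top
reaches the effect level and (ii) the derived effect concentration lies
within [lowest tested dose / 10, highest tested dose]. The lower margin
of 10 permits mild extrapolation below the ladder without allowing far
extrapolation. Flat or non-converging data yield `active = false` with a
reason string rather than an exception.

**Oxidative stress.** The low-effect region of the reporter response is
modeled linearly with the intercept forced to 1 (a solvent control has
IR 1 by definition): `IR(c) = 1 + slope·c`, and
`EC_IR1.5 = 0.5/slope` for positive slopes. The forced intercept is a
deliberate choice; it uses the definition of IR rather than spending a
degree of freedom on it.

**Masking rules.** Two rules guard against reading cytotoxicity
artifacts as specific effects:

1. Reporter-gene doses strictly above the cytotoxicity IC10 are excluded
   before the EC_IR1.5 fit (the cytotoxicity-burst problem). The mask is
   always an upper tail of the dose ladder and is idempotent; fewer than
   three retained distinct doses ⇒ inactive with reason "over-masked".
2. For MMP the cutoff is relaxed: an EC10 more than 10 × IC10 is
   suppressed as a secondary effect of cell death. The boundary is
   inclusive on the retained side (exactly 10 × IC10 is kept); the
   multiplier is configurable.

## Specificity analysis

Baseline toxicity — the minimal, hydrophobicity-driven toxicity of any
chemical — is predicted from the liposome–water distribution ratio at
pH 7.4 via `log10(1/IC10_baseline [M]) = slope·log10(D_lipw) + intercept`.
The coefficients are cell-line specific and are **required
configuration**: the package ships no defaults, tests and examples use
arbitrary illustrative values (slope 0.9, intercept 1.0), and users must
supply coefficients appropriate for their cell line.

Ratios: `TR = IC10_baseline/IC10`, `SR_cyto = IC10/EC10_mmp`,
`SR_baseline = IC10_baseline/EC10_mmp`, with the identity
`SR_baseline = TR·SR_cyto` holding to machine precision. Classification
uses a strict threshold (default 10): TR > 10 ⇒ specific cytotoxicity,
either SR > 10 ⇒ specific MMP action, both ⇒ both, all available ratios
≤ 10 ⇒ baseline-like, nothing derivable ⇒ inactive. Treating the
threshold as strict (exactly 10 is not specific) and the 10×IC10 MMP
boundary as inclusive are documented tie-break choices. All ratios are
unitless and invariant under a common rescaling of concentration units.
Water extracts (REF-scale doses) never enter this module; their
SR_cytotoxicity is reported by the water workflow as the unitless
IC10/EC10 ratio on the REF scale.

## BEQ iceberg accounting

For water extracts dosed as relative enrichment factor REF
(L water / L bioassay):

* `BEQ_bio = EC10_ref / EC10_sample` (mol reference-equivalents per litre
  of water) captures the whole measured mixture effect; an inactive
  sample yields no BEQ_bio rather than an interpolated surrogate.
* `REP_i = EC10_ref / EC10_i` and `BEQ_chem = Σ REP_i·C_i` over detected
  concentrations `C_i` (molar, on the REF = 1 basis — sample enrichment
  is applied upstream, and no correction for extraction recovery is made,
  though per-chemical recovery factors can be folded into `C_i`).
* `pct_explained = 100·BEQ_chem/BEQ_bio`; per-chemical contributions
  `BEQ_i/BEQ_chem` sum to 1.

Detected chemicals without a REP (inactive on MMP) contribute zero and
are reported in an `uncovered` list, never silently dropped. The
reference chemical is configurable (default id `24DNP`). The approach
assumes strict concentration addition, which is exact when constituents
share the mode of action and curve shape; no independent-action or
generalized-concentration-addition variants are implemented.

## Synthetic data generator

The generator reproduces the study conditions so the whole pipeline is
testable with known truth: 11-point 1:2 serial dilution, duplicate wells,
three independent runs (one independently noised plate each), a 16-well
solvent-control column, and 10,000 seeded cells per well. Expected
signals at dose c: green `G0` (1000 a.u.), red
`G0·ratio0·(1 − f_mmp(c)/100)` with control ratio 2.0, count
`N0·(1 − f_cyto(c)/100)`, luminescence `L0·(1 + slope·c)` (500 a.u.).

Noise is multiplicative lognormal with mean 1 on the optical signals
(default CV 5%, matching the design noise used throughout the validation)
and gamma-Poisson on counts (negative-binomial dispersion θ = 400, i.e.
~5% extra-Poisson CV at 10,000 cells). Lognormal multiplicative noise
keeps signals strictly positive with a realistic constant-CV structure.
Setting `signal_cv = 0` and `count_dispersion = None` makes every well
equal its expectation, and the pipeline then recovers generative effect
concentrations to optimizer tolerance (tested). All randomness flows from
the explicit seed; there is no hidden global RNG state.

Default top test concentration per chemical is `10^1.5 ×` the geometric
mean of its active-endpoint EC50s, centring the ~3-decade ladder on the
curve midpoints. Mixtures are simulated under strict concentration
addition — toxic units `T(ρ) = Σ ρ·C_i/ec50_i`, effect
`top/(1 + T^(−hill))` — which requires constituents to share top and hill
per endpoint; differing shapes raise unless an explicit `approximate`
flag accepts mean-shape curves. The detection table is emitted alongside
the wells, optionally withholding constituents to emulate unidentified
chemicals.

What the generator does **not** emulate: plate positional (edge) effects,
autofluorescence background, imaging/segmentation artifacts, per-cell
signal distributions, dose-ladder pipetting errors, or curve shapes
outside the log-logistic/linear families. Passing tests therefore
demonstrate the correctness and statistical behaviour of the evaluation
pipeline under its stated model, not robustness to instrument artifacts
that the upstream imaging workflow must handle.

## Validation and problem sizes

The statistical checks run at the study design (11 doses × 2 wells × 3
runs, 5% CV):

* EC10 recovery: 100 chemicals with ec50 spanning 6 decades (1 nM–1 mM),
  tops 70–100%, hills 1–3; median |log10(EC10_est/EC10_true)| ≈ 0.03,
  within the ≤ 0.1 requirement.
* Mixture closure: a fully detected 4-constituent equal-BEQ mixture is
  explained to ~100% (noise-free: exactly, to fitting tolerance). Because
  the closure statistic is a ratio built from five independently fitted
  EC10s, a single simulated experiment has ~13% sampling noise; the
  reported estimate is the median over 5 replicate simulations of the
  entire experiment. Withholding constituents reduces the explained
  fraction by exactly the withheld BEQ share in the noise-free limit.
* Classification recovery: 200 replicates each of a pure baseline profile
  (IC10 = QSAR prediction, EC10_mmp = IC10) and a complex-I-like profile
  (EC10_mmp 100 × below IC10, TR ≈ 1) recover `baseline_like` and
  `specific_mmp` respectively in ≥ 95% of replicates (observed: 100%).

## Degenerate inputs and numerical choices

* Fewer distinct positive doses than free parameters ⇒ `ValueError`;
  the intended design supplies 11.
* Wells with zero green signal are excluded (warning); a plate with fewer
  than 3 usable solvent controls raises.
* Duplicate chemical ids or (sample, chemical) detection pairs raise;
  unknown MIE-class strings map to `unknown` with a warning.
* All table I/O is delimited text with configurable delimiter/decimal
  (default comma/period); round trips are lossless at full float
  precision, and reader output order is independent of input row order.
* Doses are molar for chemicals and REF for extracts, disambiguated by a
  `dose_unit` column; controls carry dose 0 by schema invariant.

## Known limitations

* Single-model fitting: no model selection against alternatives (gain-
  loss, Hill variants) and no bootstrap/Bayesian confidence intervals on
  effect concentrations.
* The activity criterion (top ≥ effect level, EC within tested range) is
  an operationalization; other reasonable rules exist.
* QSAR coefficients, solubility caps, and extraction recovery corrections
  are user responsibilities; the package only provides the hooks.
* Plate layout is metadata only; no edge-effect detection or correction
  is applied.
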