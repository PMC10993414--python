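"""Curve fitting, effect-concentration inversion, and masking rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from mitooxtox import (
    Endpoint,
    EndpointMeasure,
    EndpointTruth,
    FitResult,
    GenerativeChemical,
    LogLogistic4,
    MaskInfo,
    NoiseModel,
    PlateDesign,
    derive_ec10_mmp,
    effect_conc_at,
    fit_ecir15,
    fit_loglogistic,
    induction_ratio,
    mmp_effect,
    simulate_plate,
)


def measures(doses, values, endpoint=Endpoint.MMP, tid="chemA"):
    return [
        EndpointMeasure(tid, float(d), endpoint, float(v), "run1")
        for d, v in zip(doses, values)
    ]


def ladder(top=1e-4, n=11, f=2.0):
    return top / f ** np.arange(n)


class TestFitLogLogistic:
    def test_noise_free_parameter_recovery(self):
        truth = LogLogistic4(0.0, 100.0, 1e-6, 1.5)
        doses = ladder(top=3e-5)
        fit = fit_loglogistic(measures(doses, truth(doses)))
        assert fit.active
        assert fit.params.top == pytest.approx(100.0, rel=0.01)
        assert fit.params.ec50 == pytest.approx(1e-6, rel=0.01)
        assert fit.params.hill == pytest.approx(1.5, rel=0.01)

    def test_flat_data_is_inactive(self):
        fit = fit_loglogistic(measures(ladder(), np.zeros(11)))
        assert not fit.active
        assert fit.effect_conc is None
        assert "below effect level" in fit.reason

    def test_effect_conc_outside_range_is_inactive(self):
        # curve rises only far above the tested doses
        truth = LogLogistic4(0.0, 100.0, 1.0, 1.0)
        doses = ladder(top=1e-5)
        fit = fit_loglogistic(measures(doses, truth(doses)))
        assert not fit.active

    def test_too_few_distinct_doses_raises(self):
        with pytest.raises(ValueError, match="distinct doses"):
            fit_loglogistic(measures([1e-6, 1e-6, 2e-6], [10, 12, 30]))

    def test_design_noise_ec50_recovery(self):
        """At the study design (11 doses, duplicates, 3 runs, 5% CV) ec50
        comes back within 20% for a mid-ladder curve."""
        chem = GenerativeChemical(
            "chemA", mmp=EndpointTruth(95.0, 1e-6, 1.5), cytotoxicity=None
        )
        errs = []
        for seed in range(25):
            wells = simulate_plate(
                [chem], PlateDesign(), NoiseModel(signal_cv=0.05, seed=seed),
                top_conc={"chemA": 3.2e-5},
            )
            ms = [m for m in mmp_effect(wells) if m.treatment_id == "chemA"]
            errs.append(fit_loglogistic(ms).params.ec50 / 1e-6)
        assert np.median(np.abs(np.log10(errs))) < np.log10(1.2)


class TestEffectConcAt:
    def test_closed_forms(self):
        p = LogLogistic4(0.0, 100.0, 3e-7, 1.0)
        assert effect_conc_at(p, 10.0) == pytest.approx(3e-7 / 9)
        assert effect_conc_at(p, 50.0) == pytest.approx(3e-7)

    def test_level_not_reached_raises(self):
        p = LogLogistic4(0.0, 8.0, 1e-6, 1.5)
        with pytest.raises(ValueError, match="not reached"):
            effect_conc_at(p, 10.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        top=st.floats(20, 100),
        log_ec50=st.floats(-9, -3),
        hill=st.floats(0.3, 8),
        frac=st.floats(0.05, 0.95),
    )
    def test_inversion_agrees_with_root_finding(self, top, log_ec50, hill, frac):
        p = LogLogistic4(0.0, top, 10.0**log_ec50, hill)
        level = frac * top
        c = effect_conc_at(p, level)
        c_root = brentq(
            lambda lc: float(p(10.0**lc)) - level,
            log_ec50 - 12, log_ec50 + 12, xtol=1e-13, rtol=1e-15,
        )
        assert c == pytest.approx(10.0**c_root, rel=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        top=st.floats(30, 100), hill=st.floats(0.3, 8),
        l1=st.floats(1, 25), dl=st.floats(0.5, 10),
    )
    def test_strictly_increasing_in_level(self, top, hill, l1, dl):
        p = LogLogistic4(0.0, top, 1e-6, hill)
        l2 = l1 + dl
        if l2 < top:
            assert effect_conc_at(p, l1) < effect_conc_at(p, l2)


class TestFitEcir15:
    def test_closed_form_slope(self):
        # slope 0.5 per uM -> EC_IR1.5 of 1 uM
        doses = np.array([0.2e-6, 0.5e-6, 1e-6, 2e-6, 4e-6])
        ir = 1.0 + 0.5e6 * doses
        fit = fit_ecir15(measures(doses, ir, Endpoint.OXIDATIVE_STRESS))
        assert fit.active
        assert fit.params.slope == pytest.approx(0.5e6)
        assert fit.effect_conc == pytest.approx(1e-6)

    def test_all_doses_above_ic10_over_masked(self):
        doses = np.array([1e-6, 2e-6, 4e-6, 8e-6])
        fit = fit_ecir15(measures(doses, 1 + doses * 1e6, Endpoint.OXIDATIVE_STRESS), ic10=5e-7)
        assert not fit.active
        assert fit.reason == "over-masked"
        assert set(fit.mask_info.excluded_doses) == set(doses)

    def test_mask_is_upper_tail_and_idempotent(self):
        doses = ladder(top=1e-5)
        ir = 1.0 + 2e5 * doses
        ic10 = 1.1e-6
        fit = fit_ecir15(measures(doses, ir, Endpoint.OXIDATIVE_STRESS), ic10=ic10)
        excluded = np.array(fit.mask_info.excluded_doses)
        assert (excluded > ic10).all()  # never removes doses at/below IC10
        assert set(excluded) == {d for d in doses if d > ic10}
        retained = sorted(set(doses) - set(excluded))
        refit = fit_ecir15(
            measures(retained, 1.0 + 2e5 * np.array(retained), Endpoint.OXIDATIVE_STRESS),
            ic10=ic10,
        )
        assert refit.mask_info.excluded_doses == ()  # idempotent
        assert refit.params.slope == pytest.approx(fit.params.slope)

    def test_negative_slope_inactive(self):
        doses = ladder(top=1e-5)
        fit = fit_ecir15(measures(doses, 1.0 - 1e4 * doses, Endpoint.OXIDATIVE_STRESS))
        assert not fit.active and "slope" in fit.reason

    def test_tbhq_like_recovery_at_design_noise(self):
        """Generative EC_IR1.5 = 3.14 uM; median recovery within 25% over seeds."""
        true_ec = 3.14e-6
        chem = GenerativeChemical("tBHQ", mmp=None, cytotoxicity=None, ox_slope=0.5 / true_ec)
        recovered = []
        for seed in range(100):
            wells = simulate_plate(
                [chem], PlateDesign(), NoiseModel(signal_cv=0.05, seed=seed),
                top_conc={"tBHQ": 2e-5},
            )
            ms = [m for m in induction_ratio(wells) if m.treatment_id == "tBHQ"]
            fit = fit_ecir15(ms)
            assert fit.active
            recovered.append(fit.effect_conc)
        assert np.median(np.abs(np.array(recovered) / true_ec - 1)) < 0.25


class TestSecondaryEffectRule:
    def make_fit(self, ec10):
        hill = 1.0
        top = 100.0
        ec50 = ec10 * 9.0  # level 10, bottom 0, top 100
        return FitResult(
            "chemA", Endpoint.MMP, "loglogistic4",
            LogLogistic4(0.0, top, ec50, hill), ec10, True, None, MaskInfo(), 22, 3,
        )

    @pytest.mark.parametrize(
        "ratio,retained", [(5.0, True), (10.0, True), (20.0, False)],
    )
    def test_cutoff_with_inclusive_boundary(self, ratio, retained):
        ic10 = 1e-6
        fit = derive_ec10_mmp(self.make_fit(ratio * ic10), ic10)
        assert fit.active is retained
        if not retained:
            assert fit.reason == "secondary to cytotoxicity"
            assert fit.effect_conc is None
        else:
            assert fit.effect_conc == pytest.approx(ratio * ic10)

    def test_no_ic10_passes_through(self):
        fit = self.make_fit(5e-6)
        assert derive_ec10_mmp(fit, None) is fit
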