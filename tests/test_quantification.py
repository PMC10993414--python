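"""Normalization of raw signals to per-well effects."""

import numpy as np
import pytest

from mitooxtox import (
    Endpoint,
    EndpointTruth,
    GenerativeChemical,
    NoiseModel,
    PlateDesign,
    TreatmentKind,
    WellRecord,
    cytotoxicity_effect,
    induction_ratio,
    mmp_effect,
    quantify_all,
    simulate_plate,
)


def well(wid, kind=TreatmentKind.CHEMICAL, dose=1e-6, red=2000.0, green=1000.0,
         count=10_000, lum=500.0, plate="P1"):
    kind = TreatmentKind(kind)
    return WellRecord(
        plate_id=plate, well_id=wid, treatment_id="ctrl" if kind.is_control else "chemA",
        treatment_kind=kind, dose=0.0 if kind.is_control else dose,
        dose_unit="none" if kind.is_control else "M",
        red_signal=red, green_signal=green, cell_count=count, luminescence=lum,
        run_id="run1",
    )


def controls(n=3, **kw):
    return [well(f"A{i + 1}", kind=TreatmentKind.SOLVENT_CONTROL, **kw) for i in range(n)]


def by_treatment(measures, tid="chemA"):
    return [m for m in measures if m.treatment_id == tid]


class TestMmpEffect:
    def test_control_level_ratio_gives_zero_effect(self):
        (m,) = by_treatment(mmp_effect(controls() + [well("B1", red=2000, green=1000)]))
        assert m.value == pytest.approx(0.0, abs=1e-12)

    def test_zero_red_gives_complete_loss(self):
        (m,) = by_treatment(mmp_effect(controls() + [well("B1", red=0.0)]))
        assert m.value == pytest.approx(100.0)

    @pytest.mark.parametrize("gain", [0.01, 0.5, 3.7, 1e4])
    def test_gain_invariance(self, gain, clean_plate):
        scaled = [
            WellRecord(
                **{
                    **{f: getattr(w, f) for f in w.__dataclass_fields__},
                    "red_signal": w.red_signal * gain,
                    "green_signal": w.green_signal * gain,
                    "luminescence": w.luminescence * gain,
                }
            )
            for w in clean_plate
        ]
        for fn in (mmp_effect, induction_ratio):
            base = fn(clean_plate)
            assert np.allclose(
                [m.value for m in fn(scaled)], [m.value for m in base], rtol=1e-9
            )

    def test_zero_green_well_excluded_with_warning(self):
        wells = controls() + [well("B1", green=0.0), well("B2")]
        with pytest.warns(UserWarning, match="excluded"):
            out = by_treatment(mmp_effect(wells))
        assert len(out) == 1  # only B2 survives

    def test_fewer_than_three_controls_raises(self):
        with pytest.raises(ValueError, match="solvent-control"):
            mmp_effect(controls(2) + [well("B1")])


class TestCytotoxicity:
    @pytest.mark.parametrize("count,expected", [(10_000, 0.0), (0, 100.0), (7000, 30.0)])
    def test_effect_from_counts(self, count, expected):
        (m,) = by_treatment(cytotoxicity_effect(controls() + [well("B1", count=count)]))
        assert m.value == pytest.approx(expected)

    def test_zero_mean_control_count_raises(self):
        wells = controls(count=0) + [well("B1")]
        with pytest.raises(ValueError, match="zero mean control"):
            cytotoxicity_effect(wells)

    def test_simulated_30pct_kill_recovered_within_noise(self):
        """Generative truth: 30% kill at ec50-matched dose; mean recovered effect close."""
        chem = GenerativeChemical(
            "chemA", mmp=None,
            cytotoxicity=EndpointTruth(top=60.0, ec50=1e-6, hill=1.0), ox_slope=0.0,
        )
        # at c == ec50 the curve gives top/2 = 30% kill
        wells = simulate_plate(
            [chem], PlateDesign(n_runs=3), NoiseModel(signal_cv=0.05, count_dispersion=400, seed=7),
            top_conc={"chemA": 1e-6 * 2**5},
        )
        ms = [m for m in cytotoxicity_effect(wells)
              if m.treatment_id == "chemA" and np.isclose(m.dose, 1e-6)]
        assert len(ms) == 6  # 2 tech reps x 3 runs
        assert np.mean([m.value for m in ms]) == pytest.approx(30.0, abs=5.0)


class TestInductionRatio:
    def test_control_and_threefold_wells(self):
        ms = induction_ratio(controls() + [well("B1", lum=500.0), well("B2", lum=1500.0)])
        vals = sorted(m.value for m in by_treatment(ms))
        assert vals == [pytest.approx(1.0), pytest.approx(3.0)]

    def test_linear_gradient_recovered(self):
        chem = GenerativeChemical("chemA", mmp=None, cytotoxicity=None, ox_slope=2e5)
        wells = simulate_plate(
            [chem], PlateDesign(), NoiseModel(signal_cv=0.05, count_dispersion=None, seed=3),
            top_conc={"chemA": 1e-5},
        )
        ms = by_treatment(induction_ratio(wells))
        doses = np.array([m.dose for m in ms])
        vals = np.array([m.value for m in ms])
        # per-dose means (6 replicate wells) track the generative gradient
        for d in np.unique(doses):
            assert np.mean(vals[doses == d]) == pytest.approx(1.0 + 2e5 * d, rel=0.1)
        # regression slope recovers the generative slope
        slope = float(np.sum(doses * (vals - 1)) / np.sum(doses**2))
        assert slope == pytest.approx(2e5, rel=0.1)


class TestPlateInvariants:
    def test_control_means_are_exact_per_plate(self, design, simple_chem):
        wells = simulate_plate(
            [simple_chem], design, NoiseModel(signal_cv=0.1, count_dispersion=50, seed=11)
        )
        for plate in {w.plate_id for w in wells}:
            sub = [w for w in wells if w.plate_id == plate]
            ctrl = lambda ms: [m.value for m in ms if m.treatment_id == "solvent"]
            assert np.mean(ctrl(mmp_effect(sub))) == pytest.approx(0.0, abs=1e-9)
            assert np.mean(ctrl(cytotoxicity_effect(sub))) == pytest.approx(0.0, abs=1e-9)
            assert np.mean(ctrl(induction_ratio(sub))) == pytest.approx(1.0, abs=1e-12)

    def test_quantify_all_covers_three_endpoints(self, clean_plate):
        eps = {m.endpoint for m in quantify_all(clean_plate)}
        assert eps == {Endpoint.MMP, Endpoint.CYTOTOXICITY, Endpoint.OXIDATIVE_STRESS}
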