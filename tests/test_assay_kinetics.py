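"""dAU extraction, calibration, Michaelis-Menten fitting, screening stats."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from samdcscreen.assay_kinetics import (
    DEFAULT_EPSILON_L,
    AbsorbanceTrace,
    AssayCondition,
    BackgroundFlag,
    DeltaAU,
    background_correct,
    calibrate_co2,
    delta_au,
    fit_michaelis_menten,
    inhibition_percentage,
    initial_rate,
    linearity_check,
    read_plate,
    screen_plate,
    validation_stats,
    write_plate,
)
from samdcscreen.synthetic_data import (
    AssaySimConfig,
    simulate_assay,
    simulate_standard,
)


def flat_trace(level=1.0, duration=5.0, dt=0.5, cond=None):
    t = np.arange(0, duration + dt / 2, dt)
    return AbsorbanceTrace(t, np.full_like(t, level), cond or AssayCondition())


class TestDeltaAU:
    def test_simple_subtraction(self):
        t = np.array([0.0, 5.0])
        tr = AbsorbanceTrace(t, np.array([1.000, 0.850]))
        assert delta_au(tr, 0, 5).value == pytest.approx(0.150)

    def test_flat_trace_is_zero(self):
        assert delta_au(flat_trace(), 0, 5).value == 0.0

    def test_interpolation_between_samples(self):
        # samples at 0,2,4,6 min declining 0.01 AU/min; t1=5 interpolated
        t = np.array([0.0, 2.0, 4.0, 6.0])
        tr = AbsorbanceTrace(t, 1.0 - 0.01 * t)
        assert delta_au(tr, 0, 5).value == pytest.approx(0.050, abs=1e-12)

    def test_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            delta_au(flat_trace(duration=4.0), 0, 5)

    def test_additive_under_window_split(self):
        cfg = AssaySimConfig(noise_sd=0.0, seed=1)
        tr = simulate_assay(cfg)
        total = delta_au(tr, 0, 5).value
        assert total == pytest.approx(
            delta_au(tr, 0, 2).value + delta_au(tr, 2, 5).value, abs=1e-12
        )


class TestBackgroundCorrect:
    def test_subtraction_and_flag(self):
        out = background_correct(DeltaAU(0.150), DeltaAU(0.020))
        assert out.value == pytest.approx(0.130)
        assert out.background_corrected is True

    def test_blank_equals_sample(self):
        assert background_correct(DeltaAU(0.1), DeltaAU(0.1)).value == 0.0

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            background_correct(DeltaAU(0.1, 0, 5), DeltaAU(0.1, 0, 2))

    def test_drift_only_blank_recovers_enzyme_signal(self):
        # simulator decomposition: (enzyme+drift) - (drift only) == enzyme only
        base = AssaySimConfig(noise_sd=0.0)
        full = delta_au(simulate_assay(base), 0, 5)
        blank = delta_au(simulate_assay(dataclasses.replace(base, enzyme_uM=0.0)), 0, 5)
        pure = delta_au(
            simulate_assay(dataclasses.replace(base, drift_uM_per_min=0.0)), 0, 5
        )
        assert background_correct(full, blank).value == pytest.approx(pure.value, abs=1e-9)


class TestCalibration:
    def test_linear_midpoint(self):
        standards = [(0.0, DeltaAU(0.000)), (100.0, DeltaAU(0.200))]
        est = calibrate_co2(DeltaAU(0.100), standards)
        assert est.value_uM == pytest.approx(50.0)
        assert est.extrapolated is False

    def test_sample_at_standard(self):
        standards = [(0.0, DeltaAU(0.00)), (50.0, DeltaAU(0.10)), (100.0, DeltaAU(0.20))]
        assert calibrate_co2(DeltaAU(0.10), standards).value_uM == pytest.approx(50.0)

    def test_extrapolation_flagged(self):
        standards = [(0.0, DeltaAU(0.000)), (100.0, DeltaAU(0.200))]
        assert calibrate_co2(DeltaAU(0.500), standards).extrapolated is True

    def test_degenerate_standards_rejected(self):
        with pytest.raises(ValueError):
            calibrate_co2(DeltaAU(0.1), [(50.0, DeltaAU(0.1)), (50.0, DeltaAU(0.2))])

    def test_recovered_slope_near_generator_epsilon(self):
        # noisy synthetic standards: fitted slope within 2 SE of eps*l
        cfg = AssaySimConfig(noise_sd=0.002, drift_uM_per_min=0.0)
        concs = [0.0, 25.0, 50.0, 75.0, 100.0]
        standards = [
            (c, delta_au(simulate_standard(c, dataclasses.replace(cfg, seed=i)), 0, 5))
            for i, c in enumerate(concs)
        ]
        slope, _, r2 = linearity_check(standards)
        x = np.array(concs)
        y = np.array([d.value for _, d in standards])
        from scipy.stats import linregress

        se = linregress(x, y).stderr
        assert abs(slope - DEFAULT_EPSILON_L) <= 2 * se
        assert r2 > 0.99

    def test_simulator_roundtrip_identity_noise_free(self):
        cfg = AssaySimConfig(noise_sd=0.0)
        concs = [0.0, 25.0, 50.0, 75.0, 100.0]
        standards = [(c, delta_au(simulate_standard(c, cfg), 0, 5)) for c in concs]
        for target in (10.0, 40.0, 90.0):
            sample = delta_au(simulate_standard(target, cfg), 0, 5)
            assert calibrate_co2(sample, standards).value_uM == pytest.approx(
                target, abs=1e-9
            )


class TestLinearity:
    def test_perfect_line(self):
        pairs = [(c, DeltaAU(0.002 * c + 0.01)) for c in (0.0, 50.0, 100.0, 200.0)]
        slope, intercept, r2 = linearity_check(pairs)
        assert slope == pytest.approx(0.002)
        assert intercept == pytest.approx(0.01)
        assert r2 == pytest.approx(1.0)

    def test_horizontal_points(self):
        pairs = [(c, DeltaAU(0.05)) for c in (0.0, 50.0, 100.0)]
        slope, _, _ = linearity_check(pairs)
        assert slope == pytest.approx(0.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            linearity_check([(0.0, DeltaAU(0.0)), (1.0, DeltaAU(0.1))])


class TestInitialRate:
    def test_unit_arithmetic(self):
        t = np.arange(0, 2.01, 0.25)
        tr = AbsorbanceTrace(t, 1.0 - 0.00622 * t)
        assert initial_rate(tr, window=1.0, epsilon_l=0.00622) == pytest.approx(1.0)

    def test_flat_trace(self):
        assert initial_rate(flat_trace(dt=0.25), window=1.0) == pytest.approx(0.0)

    def test_saturation_recovers_vmax(self):
        cfg = AssaySimConfig(adomet_uM=1000.0, noise_sd=0.0, drift_uM_per_min=0.0, dt=0.05)
        tr = simulate_assay(cfg)
        vmax = cfg.kcat * 60.0 * cfg.enzyme_uM
        assert initial_rate(tr, window=1.0, epsilon_l=cfg.epsilon_l) == pytest.approx(
            vmax, rel=0.01
        )

    def test_window_too_short(self):
        with pytest.raises(ValueError):
            initial_rate(flat_trace(dt=1.0), window=1.0)


FIG1D_SERIES = [0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0]


class TestMichaelisMenten:
    def test_noise_free_recovery_of_published_constants(self):
        km, kcat = 3.1, 0.062  # kcat/Km = 2.0e4 M^-1 s^-1 at Km = 3.1 uM
        vmax = kcat * 60.0 * 1.0
        points = [(s, vmax * s / (km + s)) for s in FIG1D_SERIES]
        fit = fit_michaelis_menten(points, enzyme_uM=1.0)
        assert fit.Km == pytest.approx(km, rel=1e-3)
        assert fit.kcat_over_Km == pytest.approx(2.0e4, rel=1e-3)
        assert fit.r_squared > 0.999999
        assert fit.kcat_over_Km == pytest.approx(fit.kcat / (fit.Km * 1e-6), rel=1e-9)

    def test_saturated_data_flags_km_unidentifiable(self):
        points = [(s, 2.0) for s in (500.0, 1000.0, 2000.0, 4000.0)]
        fit = fit_michaelis_menten(points, enzyme_uM=1.0)
        assert fit.Vmax == pytest.approx(2.0, rel=1e-3)
        assert fit.km_identifiable is False

    def test_too_few_distinct_concentrations(self):
        with pytest.raises(ValueError):
            fit_michaelis_menten([(1.0, 0.1), (1.0, 0.1), (2.0, 0.2), (2.0, 0.2)])

    @given(hst.floats(min_value=1.0, max_value=500.0))
    @settings(max_examples=25, deadline=None)
    def test_noise_free_recovery_sweep(self, km):
        vmax = 3.0
        series = [km * f for f in (0.1, 0.3, 1.0, 2.0, 5.0, 10.0, 30.0)]
        points = [(s, vmax * s / (km + s)) for s in series]
        fit = fit_michaelis_menten(points, enzyme_uM=1.0)
        assert fit.Km == pytest.approx(km, rel=1e-3)
        assert fit.Vmax == pytest.approx(vmax, rel=1e-3)

    def test_monte_carlo_recovery_with_noise(self):
        rng = np.random.default_rng(2024)
        km, vmax = 3.1, 3.72
        fits = []
        for _ in range(200):
            pts = [
                (s, vmax * s / (km + s) * (1 + rng.normal(0, 0.05)))
                for s in FIG1D_SERIES
                if s > 0
            ]
            fits.append(fit_michaelis_menten(pts, enzyme_uM=1.0).Km)
        assert abs(np.median(fits) - km) / km < 0.05


class TestInhibition:
    @pytest.mark.parametrize(
        "with_v,without_v,expected",
        [(0.06, 0.12, 50.0), (0.12, 0.12, 0.0), (0.0, 0.12, 100.0)],
    )
    def test_formula(self, with_v, without_v, expected):
        assert inhibition_percentage(DeltaAU(with_v), DeltaAU(without_v)) == pytest.approx(expected)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            inhibition_percentage(DeltaAU(0.1), DeltaAU(0.0))

    @given(
        hst.floats(min_value=0.0, max_value=0.2),
        hst.floats(min_value=0.0, max_value=0.2),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_signal(self, a, b):
        lo, hi = sorted((a, b))
        denom = DeltaAU(0.15)
        assert inhibition_percentage(DeltaAU(hi), denom) <= inhibition_percentage(
            DeltaAU(lo), denom
        )


class TestValidationStats:
    def test_identical_replicates(self):
        vs = validation_stats({0.0: [1.0, 1.0, 1.0]})
        assert vs.levels[0.0].cv_pct == 0.0
        assert vs.levels[0.0].sem == 0.0

    def test_hand_arithmetic_two_replicates(self):
        vs = validation_stats({50.0: [2.0, 4.0]})
        st = vs.levels[50.0]
        assert st.mean == pytest.approx(3.0)
        assert st.sd == pytest.approx(math.sqrt(2))
        assert st.cv_pct == pytest.approx(47.14, abs=0.01)
        assert st.sem == pytest.approx(1.0)

    def test_zero_mean_cv_undefined(self):
        vs = validation_stats({0.0: [-1.0, 1.0]})
        assert math.isnan(vs.levels[0.0].cv_pct)

    def test_five_pct_noise_gives_cv_near_five_pct(self):
        rng = np.random.default_rng(7)
        draws = 0.15 * (1 + rng.normal(0, 0.05, size=200))
        vs = validation_stats({80.0: list(draws)})
        assert 2.5 <= vs.cv_max <= 10.0

    @given(hst.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_cv_scale_invariant(self, c):
        base = [0.1, 0.12, 0.14]
        cv1 = validation_stats({50.0: base}).cv_mid
        cv2 = validation_stats({50.0: [c * x for x in base]}).cv_mid
        assert cv1 == pytest.approx(cv2, rel=1e-9)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            validation_stats({0.0: [1.0]})


class TestScreenPlate:
    def _well(self, cfg, cond):
        return simulate_assay(cfg, cond)

    def test_compound_identical_to_control_scores_zero(self):
        cfg = AssaySimConfig(noise_sd=0.0)
        blankcfg = dataclasses.replace(cfg, enzyme_uM=0.0, adomet_uM=0.0)
        traces = [
            simulate_assay(blankcfg, AssayCondition(well="B1", is_blank=True)),
            simulate_assay(blankcfg, AssayCondition(well="B2", is_blank=True)),
            simulate_assay(cfg, AssayCondition(well="C1", adomet_uM=1000, enzyme_uM=1.0)),
            simulate_assay(
                cfg,
                AssayCondition(
                    well="S1", adomet_uM=1000, enzyme_uM=1.0, inhibitor_id="X", inhibitor_uM=100
                ),
            ),
        ]
        res = screen_plate(traces)
        assert len(res) == 1
        assert res[0].inhibition_pct == pytest.approx(0.0, abs=1e-9)
        assert res[0].background_flag is BackgroundFlag.CLEAN

    def test_declining_no_enzyme_trace_flagged(self):
        # a compound whose blank-side trace sits far above the blanks
        cfg = AssaySimConfig(noise_sd=0.0)
        blankcfg = dataclasses.replace(cfg, enzyme_uM=0.0, adomet_uM=0.0)
        chromo = dataclasses.replace(blankcfg, compound_a340_offset=0.15)
        traces = [
            simulate_assay(blankcfg, AssayCondition(well="B1", is_blank=True)),
            simulate_assay(blankcfg, AssayCondition(well="B2", is_blank=True)),
            simulate_assay(cfg, AssayCondition(well="C1", adomet_uM=1000, enzyme_uM=1.0)),
            simulate_assay(
                dataclasses.replace(cfg, compound_a340_offset=0.15),
                AssayCondition(
                    well="S1", adomet_uM=1000, enzyme_uM=1.0, inhibitor_id="X", inhibitor_uM=100
                ),
            ),
        ]
        bg = [
            simulate_assay(
                chromo, AssayCondition(well="BG1", inhibitor_id="X", inhibitor_uM=100)
            )
        ]
        res = screen_plate(traces, bg)
        assert res[0].background_flag is BackgroundFlag.ABSORBANCE_INTERFERENCE

    def test_missing_control_rejected(self):
        cfg = AssaySimConfig(noise_sd=0.0, enzyme_uM=0.0, adomet_uM=0.0)
        blanks = [simulate_assay(cfg, AssayCondition(well="B1", is_blank=True))]
        with pytest.raises(ValueError, match="control"):
            screen_plate(blanks)


class TestPlateIO:
    def test_roundtrip(self, tmp_path):
        cfg = AssaySimConfig(noise_sd=0.002, seed=5)
        traces = [
            simulate_assay(cfg, AssayCondition(well="A1", adomet_uM=1000, enzyme_uM=1.0)),
            simulate_assay(
                dataclasses.replace(cfg, enzyme_uM=0.0, adomet_uM=0.0, seed=6),
                AssayCondition(well="A2", is_blank=True),
            ),
        ]
        write_plate(traces, tmp_path / "p.tsv", tmp_path / "c.tsv")
        back = read_plate(tmp_path / "p.tsv", tmp_path / "c.tsv")
        assert [tr.condition.well for tr in back] == ["A1", "A2"]
        assert back[1].condition.is_blank is True
        assert back[0].condition.enzyme_uM == 1.0
        np.testing.assert_allclose(back[0].a340, traces[0].a340, atol=1e-6)
        np.testing.assert_allclose(back[0].times, traces[0].times, atol=1e-9)
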