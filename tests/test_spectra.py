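"""Unit and property tests for the QMS response model and deconvolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import syngaspat as sg
from syngaspat.spectra import ConfigurationError


class TestResponseMatrix:
    def test_single_gas_identity(self):
        lib = sg.FragmentationLibrary({"N2": {28: 1.0, 14: 0.072}})
        sens = sg.SensitivitySet({"N2": 1.0})
        A = sg.response_matrix(lib, sens, [28, 14])
        assert A.tolist() == [[1.0], [0.072]]

    def test_two_gas_structure(self):
        lib = sg.FragmentationLibrary({"CO": {28: 1.0, 12: 0.045}, "N2": {28: 1.0, 14: 0.072}})
        sens = sg.SensitivitySet({"CO": 1.0, "N2": 1.0})
        # documented column order: canonical, CO before N2
        A = sg.response_matrix(lib, sens, [28, 14, 12])
        assert A.tolist() == [[1.0, 1.0], [0.0, 0.072], [0.045, 0.0]]

    def test_sensitivity_scales_columns(self):
        lib = sg.FragmentationLibrary({"CO": {28: 1.0, 12: 0.045}, "N2": {28: 1.0, 14: 0.072}})
        sens = sg.SensitivitySet({"CO": 2.0, "N2": 1.0})
        A = sg.response_matrix(lib, sens, [28, 12])
        assert A[:, 0].tolist() == [2.0, 0.09]

    def test_default_library_full_rank(self, lib, unit_sens):
        A = sg.response_matrix(lib, unit_sens, lib.channel_union)
        assert np.linalg.matrix_rank(A) == len(sg.GASES)

    def test_unknown_gas_and_duplicate_channel_rejected(self, lib):
        with pytest.raises(ConfigurationError):
            sg.response_matrix(lib, sg.SensitivitySet({"N2": 1.0, "CH4": 0.9}), [28, 16])
        with pytest.raises(ValueError):
            sg.response_matrix(lib, sg.SensitivitySet.unit(), [28, 28])


@pytest.mark.parametrize(
    "scan, bg, expected",
    [
        ({28: 5.0}, {28: 5.0}, {28: 0.0}),
        ({28: 5.0}, {28: 6.0}, {28: 0.0}),
        ({28: 5.0, 44: 2.0}, {28: 1.0}, {28: 4.0, 44: 2.0}),
    ],
)
def test_subtract_background(scan, bg, expected):
    out = sg.subtract_background(sg.ChannelSpectrum(scan), sg.BackgroundProfile(bg))
    assert out.intensities == expected


class TestDeconvolve:
    def test_pure_n2(self, lib, unit_sens):
        scan = sg.synthesize_spectrum(sg.GasComposition({"N2": 100.0}), lib, unit_sens)
        res = sg.deconvolve(scan, lib, unit_sens)
        assert res.composition["N2"] == pytest.approx(100.0, abs=1e-9)
        assert res.relative_residual == pytest.approx(0.0, abs=1e-12)

    def test_syngas_noise_free_recovery(self, lib, unit_sens, syngas):
        scan = sg.synthesize_spectrum(syngas, lib, unit_sens)
        res = sg.deconvolve(scan, lib, unit_sens)
        for g, expected in (("CO", 25.0), ("H2", 25.0), ("CO2", 5.0), ("N2", 45.0)):
            assert res.composition[g] == pytest.approx(expected, rel=1e-6)
        assert not res.residual_flag

    def test_empty_spectrum_rejected(self, lib, unit_sens):
        with pytest.raises(ValueError, match="empty spectrum"):
            sg.deconvolve(sg.ChannelSpectrum({28: 0.0, 44: 0.0}), lib, unit_sens)

    def test_orphan_channels_warn_not_fail(self, lib, unit_sens):
        scan = sg.synthesize_spectrum(sg.GasComposition({"N2": 100.0}), lib, unit_sens)
        with_orphan = sg.ChannelSpectrum({**scan.intensities, 99: 3.0})
        with pytest.warns(UserWarning, match="no library entry"):
            res = sg.deconvolve(with_orphan, lib, unit_sens)
        assert res.composition["N2"] == pytest.approx(100.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, lib, unit_sens, noisy_scan):
        """NNLS agrees with an exhaustive 0.1 %-step scan of the same objective."""
        truth = sg.GasComposition({"CO": 30.0, "N2": 70.0})
        gases = ("CO", "N2")
        for seed in range(5):
            scan = noisy_scan(truth, unit_sens, 100 + seed, sigma=0.01)
            channels = scan.channels
            y = np.array([scan.intensities[m] for m in channels])
            A = sg.response_matrix(lib, unit_sens, channels, gases)

            best_x, best_r = None, np.inf
            for x in np.arange(0.0, 100.0 + 1e-9, 0.1):
                u = A @ np.array([x, 100.0 - x]) / 100.0
                s = max(float(u @ y) / float(u @ u), 0.0)
                r = float(np.linalg.norm(s * u - y))
                if r < best_r:
                    best_x, best_r = x, r

            res = sg.deconvolve(scan, lib, unit_sens, gases=gases)
            assert res.composition["CO"] == pytest.approx(best_x, abs=0.1 + 1e-9)

    @settings(max_examples=30, deadline=None)
    @given(
        raw=st.lists(
            st.floats(min_value=1.0, max_value=100.0), min_size=len(sg.GASES), max_size=len(sg.GASES)
        )
    )
    def test_roundtrip_and_normalization(self, lib, unit_sens, raw):
        """Noise-free synthesize -> deconvolve is the identity; output sums to 100."""
        comp = sg.GasComposition(dict(zip(sg.GASES, raw))).normalized()
        res = sg.deconvolve(sg.synthesize_spectrum(comp, lib, unit_sens), lib, unit_sens)
        assert res.composition.total() == pytest.approx(100.0, abs=1e-6)
        for g in sg.GASES:
            assert res.composition[g] == pytest.approx(comp[g], rel=1e-6, abs=1e-6)

    def test_gas_order_permutation_invariance(self, lib, unit_sens, syngas):
        scan = sg.synthesize_spectrum(syngas, lib, unit_sens)
        a = sg.deconvolve(scan, lib, unit_sens, gases=("H2", "CO", "CO2", "N2", "H2O", "O2", "AR"))
        b = sg.deconvolve(scan, lib, unit_sens, gases=("AR", "N2", "CO", "O2", "H2O", "H2", "CO2"))
        for g in sg.GASES:
            assert a.composition[g] == pytest.approx(b.composition[g], abs=1e-9)

    def test_error_monotone_in_noise(self, lib, unit_sens, syngas):
        """Mean recovery error does not decrease as channel noise grows."""
        clean = sg.synthesize_spectrum(syngas, lib, unit_sens)
        channels = clean.channels
        base = np.array([clean.intensities[m] for m in channels])
        means = []
        for sigma in (0.0, 0.005, 0.02):
            errs = []
            for seed in range(40):
                eps = np.random.default_rng(seed).standard_normal(len(base))
                scan = sg.ChannelSpectrum(dict(zip(channels, np.maximum(base * (1 + sigma * eps), 0))))
                res = sg.deconvolve(scan, lib, unit_sens)
                rep = sg.verify_accuracy(syngas, res.composition)
                errs.append(rep.max_relative_error)
            means.append(np.mean(errs))
        assert means[0] <= means[1] <= means[2]


class TestCalibration:
    def test_identity_recovery(self, lib, unit_sens, syngas):
        air = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.5))
        cyl = sg.GasComposition({"CO2": 15.0, "O2": 21.0, "N2": 64.0})
        refs = [
            (sg.synthesize_spectrum(c, lib, unit_sens), c) for c in (air, cyl, syngas)
        ]
        cal = sg.calibrate_sensitivities(refs, lib)
        for g in sg.GASES:
            assert cal[g] == pytest.approx(1.0, abs=1e-9)

    def test_known_sensitivity_roundtrip(self, lib, varied_sens, syngas):
        air = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.5))
        cyl = sg.GasComposition({"CO2": 15.0, "O2": 21.0, "N2": 64.0})
        refs = [
            (sg.synthesize_spectrum(c, lib, varied_sens), c) for c in (air, cyl, syngas)
        ]
        cal = sg.calibrate_sensitivities(refs, lib)
        for g in sg.GASES:
            assert cal[g] == pytest.approx(varied_sens[g], rel=1e-9)

    def test_noisy_recovery_within_5_percent(self, lib, varied_sens, syngas, noisy_scan):
        """Monte-Carlo: 1 % channel noise keeps mean per-gas recovery within 5 %."""
        air = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.5))
        cyl = sg.GasComposition({"CO2": 15.0, "O2": 21.0, "N2": 64.0})
        devs = {g: [] for g in sg.GASES}
        for seed in range(100):
            refs = [
                (noisy_scan(c, varied_sens, 1000 * seed + i), c)
                for i, c in enumerate((air, cyl, syngas))
            ]
            cal = sg.calibrate_sensitivities(refs, lib)
            for g in sg.GASES:
                devs[g].append(abs(cal[g] - varied_sens[g]) / varied_sens[g])
        for g, d in devs.items():
            assert np.mean(d) <= 0.05, f"{g} mean recovery error {np.mean(d):.3f}"

    def test_unobserved_gas_rejected(self, lib, unit_sens):
        n2 = sg.GasComposition({"N2": 100.0})
        refs = [(sg.synthesize_spectrum(n2, lib, unit_sens), n2)]
        with pytest.raises(ValueError, match="CO never observed"):
            sg.calibrate_sensitivities(refs, lib, gases=("CO", "N2"))

    def test_missing_inert_gas_rejected(self, lib, unit_sens):
        co = sg.GasComposition({"CO": 100.0})
        refs = [(sg.synthesize_spectrum(co, lib, unit_sens), co)]
        with pytest.raises(ValueError, match="N2 must be present"):
            sg.calibrate_sensitivities(refs, lib, gases=("CO",))


class TestHumidAir:
    def test_zero_humidity_is_identity(self):
        dry = sg.GasComposition(sg.spectra.DRY_AIR_PERCENTS).normalized()
        out = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.0), dry)
        for g in dry.gases:
            assert out[g] == pytest.approx(dry[g], rel=1e-12)
        assert out["H2O"] == 0.0

    def test_buck_matches_published_saturation_pressure(self):
        # Saturation vapour pressure of water at 25 C is about 3.17 kPa.
        assert sg.buck_vapour_pressure_kpa(25.0) == pytest.approx(3.17, rel=0.005)

    def test_room_conditions_water_fraction(self):
        out = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.5))
        # oracle: 100 * 0.5 * 3.17 kPa / 101.325 kPa
        assert out["H2O"] == pytest.approx(100 * 0.5 * 3.17 / 101.325, rel=0.01)
        assert out.total() == pytest.approx(100.0, abs=1e-9)

    def test_wet_reference_rejected(self):
        wet = sg.GasComposition({"N2": 79.0, "O2": 20.0, "H2O": 1.0})
        with pytest.raises(ValueError, match="zero H2O"):
            sg.humid_air_composition(sg.AmbientConditions(25.0), wet)


class TestVerifyAccuracy:
    def test_identical_compositions_pass(self, syngas):
        rep = sg.verify_accuracy(syngas, syngas)
        assert rep.max_relative_error == 0.0
        assert rep.passed

    def test_relative_error_arithmetic(self):
        known = sg.GasComposition({"CO": 25.0, "N2": 75.0})
        measured = sg.GasComposition({"CO": 26.0, "N2": 74.0})
        rep = sg.verify_accuracy(known, measured)
        assert rep.relative_errors["CO"] == pytest.approx(0.04)
        assert rep.passed  # 4 % clears the 8 % gate

    def test_absent_gas_reported_absolutely(self):
        known = sg.GasComposition({"CO": 0.0, "N2": 100.0})
        measured = sg.GasComposition({"CO": 0.5, "N2": 99.5})
        rep = sg.verify_accuracy(known, measured)
        assert "CO" not in rep.relative_errors
        assert rep.absolute_errors["CO"] == pytest.approx(0.5)
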