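import numpy as np
import pytest

import syngaspat as sg

#: Response factors used as ground truth when testing calibration recovery;
#: deliberately far from unity so normalization errors cannot hide.
VARIED_SENSITIVITIES = {
    "H2": 0.4,
    "CO": 1.05,
    "CO2": 1.4,
    "N2": 1.0,
    "H2O": 0.8,
    "O2": 0.9,
    "AR": 1.2,
}

SYNGAS = {"CO": 25.0, "H2": 25.0, "CO2": 5.0, "N2": 45.0}


@pytest.fixture(scope="session")
def lib():
    return sg.FragmentationLibrary.default()


@pytest.fixture(scope="session")
def unit_sens():
    return sg.SensitivitySet.unit()


@pytest.fixture(scope="session")
def varied_sens():
    return sg.SensitivitySet(VARIED_SENSITIVITIES)


@pytest.fixture(scope="session")
def syngas():
    return sg.GasComposition(SYNGAS, label="syngas feed")


@pytest.fixture(scope="session")
def noisy_scan(lib):
    """Factory: synthesize a scan for a composition with multiplicative channel noise."""

    def make(composition, sens, seed, sigma=0.01):
        rng = np.random.default_rng(seed)
        clean = sg.synthesize_spectrum(composition, lib, sens)
        return sg.ChannelSpectrum(
            {
                mz: max(v * (1.0 + sigma * rng.standard_normal()), 0.0)
                for mz, v in clean.intensities.items()
            }
        )

    return make


@pytest.fixture(scope="session")
def reference_scans(lib, varied_sens, syngas, noisy_scan):
    """The three calibration references: humid air, CO2/O2/N2 cylinder, syngas."""
    air = sg.humid_air_composition(sg.AmbientConditions(25.0, 101.325, 0.5))
    cylinder = sg.GasComposition({"CO2": 15.0, "O2": 21.0, "N2": 64.0}, label="CO2/O2/N2")
    return [
        (noisy_scan(comp, varied_sens, seed), comp)
        for seed, comp in enumerate((air, cylinder, syngas))
    ]


@pytest.fixture(scope="session")
def calibrated_sens(reference_scans, lib):
    return sg.calibrate_sensitivities(reference_scans, lib)


@pytest.fixture(scope="session")
def batch_result():
    return sg.run(sg.batch_scenario())


@pytest.fixture(scope="session")
def chemostat_result():
    return sg.run(sg.chemostat_scenario())


@pytest.fixture(scope="session")
def fed_batch_result():
    return sg.run(sg.fed_batch_scenario())
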