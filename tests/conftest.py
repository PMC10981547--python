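import numpy as np
import pytest

from tonguecolor.io import load_example_biometrics, load_example_lab_pairs

#: published per-patient dE00 values of the example cohort's report table,
#: keyed by patient id (printed at one decimal)
PRINTED_DE00 = {
    "1": 2.1, "2": 1.3, "3": 2.7, "4": 6.8, "5": 3.7, "6": 1.3,
    "7": 5.6, "8": 1.5, "9": 1.4, "10": 2.0, "11": 2.6, "12": 4.1,
    "13": 2.1, "14": 3.6, "15": 6.1, "16": 1.1, "17": 2.5, "18": 0.5,
}

#: published signed components (dL', dC', dH') for the same rows
PRINTED_COMPONENTS = {
    "1": (1.47, 1.46, 2.26), "2": (-1.20, 0.82, -0.93), "3": (0.58, 4.43, 3.02),
    "4": (7.49, 1.78, 2.64), "5": (3.24, 2.35, 2.70), "6": (-0.46, 2.22, -1.09),
    "7": (5.51, 3.67, 1.50), "8": (0.70, 2.74, 1.26), "9": (-0.67, 2.95, 0.80),
    "10": (-1.41, 3.36, 0.42), "11": (-2.60, 1.43, -0.73), "12": (-4.38, 2.43, -1.17),
    "13": (-2.27, 1.88, -0.07), "14": (-3.94, 1.89, -0.98), "15": (-6.09, 2.01, -1.39),
    "16": (-0.60, 2.29, 0.42), "17": (2.36, 3.04, 0.24), "18": (-0.30, 1.02, 0.17),
}


@pytest.fixture(scope="session")
def example_pairs():
    """Paired sitting/supine edge Lab measurements of the bundled cohort."""
    return load_example_lab_pairs()


@pytest.fixture(scope="session")
def example_biometrics():
    """Biometric records of the bundled 18-patient cohort."""
    return load_example_biometrics()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240323)
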