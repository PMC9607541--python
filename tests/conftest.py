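import numpy as np
import pytest

from fluorbind import SyntheticConfig, simulate_titration_series

# Published fluorescence parameters of the albumin-ligand system used as
# ground truth throughout: Ksv/Kq at 298 and 308 K, binding constants and
# site numbers from the double-log fit, and the van't Hoff pair.
PUBLISHED = {
    "Ksv": {298.0: 1.21e5, 308.0: 0.41e5},
    "Kq": {298.0: 1.21e13, 308.0: 0.41e13},
    "n": {298.0: 1.50, 308.0: 1.35},
    "Ka": {298.0: 3.79e4, 308.0: 1.93e4},
    "dG": {298.0: -26.12, 308.0: -24.45},
    "dH": -51.53,
    "dS": {298.0: -85.25, 308.0: -87.91},
}

# Probe-displacement constants (1e4 L/mol) and printed K'a/Ka percentages.
PROBE_CONSTANTS = {
    "methyl orange": {"Ka_prime": 1.79e4, "ratio": 45.00},
    "warfarin": {"Ka_prime": 0.98e4, "ratio": 25.76},
    "ibuprofen": {"Ka_prime": 3.38e4, "ratio": 89.23},
}
KA_FREE = 3.79e4


@pytest.fixture
def noiseless_sv_series():
    return simulate_titration_series(SyntheticConfig(mode="stern_volmer"))


@pytest.fixture
def noiseless_hill_series():
    return simulate_titration_series(SyntheticConfig(mode="hill_binding"))
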