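import numpy as np
import pytest

from tgmo import DrugSpec, generate_oacd


@pytest.fixture(scope="session")
def k3_design():
    return generate_oacd(["alpha", "beta", "gamma"], seed=7)


@pytest.fixture(scope="session")
def k4_design():
    return generate_oacd(["a", "b", "c", "d"], seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def renal_specs():
    """Dose table of the renal screen panel at the published screen doses."""
    from tgmo import CLINICAL_DOSES_UM

    screen = {
        "crizotinib": 0.664,
        "telaglenastat": 0.013,
        "u104": 9.524,
        "vismodegib": 12.754,
    }
    return {
        d: DrugSpec(drug=d, cud_uM=CLINICAL_DOSES_UM[d], screen_dose_uM=dose)
        for d, dose in screen.items()
    }
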