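import numpy as np
import pytest

from tightknot import massspec, synthetic

STUDY_KD = 30.25          # nM, ground truth used across titration fixtures
STUDY_ET = 515.0          # nM, trypsin at 12 ng/uL and MW 23,300 Da
PRINTED_TRIO = (1102.4051, 1239.9110, 1417.0741)   # observed ESI envelope (m/z)


@pytest.fixture(scope="session")
def coarse_noiseless_series():
    """Study-design grid (0-4 uM, 0.25 uM steps), no noise, single replicate."""
    spec = synthetic.TitrationSimSpec(true_kd=STUDY_KD, enzyme_total=STUDY_ET,
                                      noise_cv=0.0, n_replicates=1)
    return synthetic.gen_titration(spec)


@pytest.fixture(scope="session")
def dense_noiseless_series():
    grid = tuple(float(x) for x in range(0, 4001, 5))
    spec = synthetic.TitrationSimSpec(true_kd=STUDY_KD, enzyme_total=STUDY_ET,
                                      inhibitor_grid=grid, noise_cv=0.0,
                                      n_replicates=1)
    return synthetic.gen_titration(spec)


@pytest.fixture
def printed_trio_envelope():
    return massspec.IonEnvelope(np.array(PRINTED_TRIO))
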