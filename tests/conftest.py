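import numpy as np
import pytest

from numadapt.design import make_tuned_grid, tuned_basis
from numadapt.hrf import HrfSpec
from numadapt.stimuli import build_run_sequence, mean_power_table


@pytest.fixture(scope="session")
def sequences():
    """One run sequence per adaptor condition (deterministic, seed 0)."""
    return {c: build_run_sequence(c) for c in ("low", "high", "changing")}


@pytest.fixture(scope="session")
def power_table():
    """Mean aggregate Fourier power per numerosity (20 displays each)."""
    return mean_power_table(seed=0)


@pytest.fixture(scope="session")
def hrf():
    return HrfSpec()


@pytest.fixture(scope="session")
def full_grid():
    """The full tuned-model candidate grid (shared: amplitude caches are
    reused across tests)."""
    return make_tuned_grid()


@pytest.fixture(scope="session")
def changing_basis(sequences, hrf):
    return tuned_basis(sequences["changing"], hrf)


@pytest.fixture(scope="session")
def changing_design(sequences, power_table, hrf):
    from numadapt.design import build_design

    return build_design(sequences["changing"], "monotonic", hrf=hrf,
                        power_table=power_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
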