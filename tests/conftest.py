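import numpy as np
import pytest

from qdhfold import restraints as R
from qdhfold import synthetic_data as S
from qdhfold import topology as T


@pytest.fixture(scope="session")
def form1():
    return T.build_form1_topology()


@pytest.fixture(scope="session")
def form2():
    return T.build_form2_topology()


@pytest.fixture(scope="session")
def form1_reference(form1):
    """Idealized Form 1 all-atom reference (expensive; built once)."""
    return S.build_idealized_coords(form1)


@pytest.fixture(scope="session")
def form2_reference(form2):
    return S.build_idealized_coords(form2)


@pytest.fixture(scope="session")
def form1_restraints(form1, form1_reference):
    """Noise-free restraint set generated from the Form 1 reference."""
    noise = S.NoiseModel(distance_jitter_sd=0.0, false_negative_rate=0.0, seed=0)
    peaks = S.simulate_noe_peaks(form1_reference, max_distance=6.0, noise=noise)
    return {
        "noe": R.peaks_to_restraints(peaks),
        "hbond": R.hbond_restraints(form1),
        "dihedral": R.dihedral_restraints(form1),
        "planarity": R.planarity_restraints(form1),
    }
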