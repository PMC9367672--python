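import numpy as np
import pytest

from dmpkit.kinetics import KineticDataset, mm_velocity, substrate_inhibition_velocity

S_GRID_8 = np.geomspace(1.0, 200.0, 8)
S_GRID_10 = np.geomspace(1.0, 200.0, 10)

# printed mean kinetic parameters used as ground truths throughout the tests
HLMS_MM = (35.07, 244.63)  # Vmax pmol/min/mg, Km µM
RLMS_MM = (158.26, 121.13)
SI_TRUTH = (100.0, 50.0, 200.0)  # Vmax, Ks, Ksi
BIPHASIC_TRUTH = (10.0, 5.0, 100.0, 500.0)  # Vmax1, Ks1, Vmax2, Ks2


@pytest.fixture
def mm_dataset():
    """Noise-free Michaelis–Menten data on the 8-point 1–200 µM design."""
    return KineticDataset(
        enzyme_source="human",
        metabolite_id="P4",
        concentrations=S_GRID_8,
        velocities=mm_velocity(S_GRID_8, *HLMS_MM),
    )


@pytest.fixture
def si_dataset():
    """Noise-free substrate-inhibition data on a 10-point design."""
    return KineticDataset(
        enzyme_source="dog",
        metabolite_id="P4",
        concentrations=S_GRID_10,
        velocities=substrate_inhibition_velocity(S_GRID_10, *SI_TRUTH),
    )
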