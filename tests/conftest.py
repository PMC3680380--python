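import numpy as np
import pytest

from planarpore.gatingsim import (
    EnsembleConfig,
    GatingScheme,
    RecordingConfig,
    simulate_experiment,
)
from planarpore.iontransport import IonSpecies, SolutionPair


@pytest.fixture(scope="session")
def kcl_gradient_pair():
    """810 mM KCl cis / 210 mM trans at 22 C, P_K/P_Cl = 3.03."""
    return SolutionPair(
        species=(
            IonSpecies("K", 1, 810.0, 210.0, permeability=3.03),
            IonSpecies("Cl", -1, 810.0, 210.0, permeability=1.0),
        ),
        temperature=295.15,
    )


@pytest.fixture(scope="session")
def three_channel_sim():
    """A 30-s, 3-channel recording at -40 mV with known ground truth.

    Session-scoped: several tests reuse the same simulated experiment.
    """
    scheme = GatingScheme.two_state(k_co=40.0, k_oc=10.0)  # Po = 0.8
    ens = EnsembleConfig(scheme=scheme, n_channels=3, conductance=395.0)
    rec = RecordingConfig(holding_potential=-40.0, duration=30.0)
    trace, seq = simulate_experiment(ens, rec, seed=20260923)
    return {"trace": trace, "seq": seq, "ens": ens, "rec": rec, "scheme": scheme}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
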