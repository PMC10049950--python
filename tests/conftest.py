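import pytest

from fabstab.synthetic import (ToyFabSpec, ToyPotential, build_toy_fab,
                               generate_bound_ensemble,
                               generate_dissociation_trajectory)


@pytest.fixture(scope="session")
def fab():
    return build_toy_fab(ToyFabSpec(seed=7))


@pytest.fixture(scope="session")
def rigid_traj(fab):
    return generate_dissociation_trajectory(fab, "rigid", n_frames=11,
                                            noise_sigma=0.0, final_offset=2.0)


@pytest.fixture(scope="session")
def bound_trace():
    return generate_bound_ensemble(n_frames=20_000, seed=3)


@pytest.fixture(scope="session")
def morse():
    return ToyPotential("morse_well", depth=5.0, width=6.0, r0=2.0,
                        domain=(1.6, 4.2))


@pytest.fixture(scope="session")
def flat():
    return ToyPotential("flat", domain=(0.0, 4.0))
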