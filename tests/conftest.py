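import numpy as np
import pytest

from nmathresh import (
    NetworkData,
    PriorSpec,
    SimulationSpec,
    Study,
    generate,
)


def make_network(seed, K=4, n_studies=8, tau2=0.0, multi_arm_fraction=0.3):
    net, truth = generate(
        SimulationSpec(
            K=K,
            n_studies=n_studies,
            multi_arm_fraction=multi_arm_fraction,
            tau2_true=tau2,
            seed=seed,
        )
    )
    return net


def has_three_arm(net):
    return any(s.n_arms >= 3 for s in net.studies)


def network_with_three_arm(seed, K=4, n_studies=8, tau2=0.0):
    """Random connected network guaranteed to include a three-arm study."""
    for s in range(seed, seed + 100):
        net = make_network(s, K=K, n_studies=n_studies, tau2=tau2,
                          multi_arm_fraction=0.4)
        if has_three_arm(net):
            return net
    raise RuntimeError("no three-arm network found")


@pytest.fixture
def two_treatment_single_datum():
    """K=2, one study, one datum: everything is scalar and checkable by hand."""
    study = Study(id="S1", treatments=[1, 2], y=[0.5], V=[[0.2]])
    return NetworkData(studies=[study])


@pytest.fixture
def two_treatment_two_data():
    s1 = Study(id="S1", treatments=[1, 2], y=[0.4], V=[[0.1]])
    s2 = Study(id="S2", treatments=[1, 2], y=[1.0], V=[[0.3]])
    return NetworkData(studies=[s1, s2])


@pytest.fixture
def complete_three_network():
    """Complete 3-treatment network, one study per edge."""
    studies = [
        Study(id="S12", treatments=[1, 2], y=[0.3], V=[[0.10]]),
        Study(id="S13", treatments=[1, 3], y=[0.9], V=[[0.15]]),
        Study(id="S23", treatments=[2, 3], y=[0.5], V=[[0.20]]),
    ]
    return NetworkData(studies=studies)


@pytest.fixture
def mixed_network():
    """4 treatments, three 2-arm studies and one 3-arm study."""
    studies = [
        Study(id="A", treatments=[1, 2], y=[0.2], V=[[0.1]]),
        Study(id="B", treatments=[2, 3], y=[0.4], V=[[0.2]]),
        Study(
            id="C",
            treatments=[1, 3, 4],
            y=[0.6, 0.1],
            V=[[0.3, 0.1], [0.1, 0.25]],
        ),
        Study(id="D", treatments=[3, 4], y=[-0.2], V=[[0.15]]),
    ]
    return NetworkData(studies=studies)


@pytest.fixture
def flat_prior():
    return PriorSpec.flat
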