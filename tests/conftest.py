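import numpy as np
import pytest

from misclassim import SimCondition, Topology, simulate_condition


def make_dataset(n_total=150, ratio=(50, 50, 50), d=0.8, pi=0.0,
                 topology="AB_BC", seed=0, eligibility_mode="strict"):
    cond = SimCondition(Topology.from_name(topology, eligibility_mode),
                        n_total, ratio, d, pi, seed=seed)
    return simulate_condition(cond)


@pytest.fixture
def clean_dataset():
    """Equal groups, moderate separation, no label noise."""
    return make_dataset(seed=42)


@pytest.fixture
def noisy_dataset():
    """Equal groups, adjacent-group mislabeling at 20%."""
    return make_dataset(pi=0.2, seed=42)
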