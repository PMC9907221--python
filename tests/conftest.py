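import numpy as np
import pytest

from pepppo import build_profiles, make_hidden_oracle, synth_binding_dataset
from pepppo.policy import MutationPolicy, PolicyConfig
from pepppo.encoding import EncodingConfig


@pytest.fixture(scope="session")
def oracle():
    """Small hidden-motif oracle: 3 alleles, 9-mers, 4 anchors at kappa 0.9."""
    return make_hidden_oracle(n_alleles=3, lengths=(9,), n_anchors=4, kappa=0.9, seed=7)


@pytest.fixture(scope="session")
def alleles(oracle):
    return list(oracle.alleles.values())


@pytest.fixture(scope="session")
def binding_dataset(oracle):
    return synth_binding_dataset(oracle, n_per_allele=200, seed=11)


@pytest.fixture(scope="session")
def expert_table(oracle, alleles, binding_dataset):
    return build_profiles(binding_dataset, registry={m.name: m for m in alleles})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def tiny_policy():
    """Small network for fast unit tests."""
    cfg = PolicyConfig(hidden=8, mhc_hidden=16, mhc_dim=8, head_hidden=8, value_hidden=8,
                       encoding=EncodingConfig(learned_dim=4))
    return MutationPolicy(cfg, seed=1)
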