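import numpy as np
import pytest

from dosecmap import (GeneSignature, PerturbationProfile, SignatureDatabase,
                      SimConfig, simulate_study)


@pytest.fixture(scope="session")
def small_study():
    """A scaled-down synthetic screen shared by read-only tests."""
    return simulate_study(SimConfig(seed=11, n_landmark=300, n_null_drugs=30,
                                    n_sig_up=20, n_sig_down=20,
                                    n_noise_genes=80, n_terms=30,
                                    planted_term_size=10))


@pytest.fixture
def tiny_universe():
    return tuple("ABCDEFGHIJ")


def make_profile(universe, values, drug="D1", dose=1.0, dur=24.0, rep=1):
    return PerturbationProfile(drug_id=drug, dose_um=dose, duration_h=dur,
                               replicate=rep, universe=tuple(universe),
                               values=np.asarray(values, dtype=float))


@pytest.fixture
def tiny_profile(tiny_universe):
    rng = np.random.default_rng(5)
    return make_profile(tiny_universe, rng.normal(size=len(tiny_universe)))


@pytest.fixture
def tiny_db(tiny_universe):
    rng = np.random.default_rng(7)
    profiles = [make_profile(tiny_universe, rng.normal(size=10),
                             drug=f"D{i}", dose=float(i + 1), rep=1)
                for i in range(4)]
    return SignatureDatabase(universe=tiny_universe, profiles=profiles)


@pytest.fixture
def simple_signature():
    return GeneSignature(up=frozenset({"A", "B"}), down=frozenset({"C", "D"}))
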