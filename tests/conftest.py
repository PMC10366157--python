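import numpy as np
import pytest

from famagg.pedigree import Individual, Pedigree
from famagg.simulate import SimulationConfig, simulate_pedigrees


def make_extended_pedigree() -> Pedigree:
    """Hand-built family exhibiting all twelve pair classes (non-inbred).

    Three founder-couple branches: U's child N and A's children C1/C2 are
    first cousins; B has children H1/H2 by two different wives.
    """
    rows = [
        # iid, father, mother, sex
        ("GF", None, None, "male"),
        ("GM", None, None, "female"),
        ("U", "GF", "GM", "male"),
        ("A", "GF", "GM", "female"),
        ("B", "GF", "GM", "male"),
        ("UW", None, None, "female"),
        ("N", "U", "UW", "female"),
        ("AH", None, None, "male"),
        ("C1", "AH", "A", "male"),
        ("C2", "AH", "A", "female"),
        ("C3", "AH", "A", "female"),
        ("W1", None, None, "female"),
        ("H1", "B", "W1", "male"),
        ("W2", None, None, "female"),
        ("H2", "B", "W2", "female"),
    ]
    return Pedigree(
        Individual(iid, "FAM1", f, m, s) for iid, f, m, s in rows
    )


def make_inbred_pedigree() -> Pedigree:
    """First-cousin parents and their child (f = 1/16)."""
    rows = [
        ("GF", None, None, "male"),
        ("GM", None, None, "female"),
        ("S1", "GF", "GM", "male"),
        ("S2", "GF", "GM", "female"),
        ("S1W", None, None, "female"),
        ("S2H", None, None, "male"),
        ("K1", "S1", "S1W", "male"),
        ("K2", "S2H", "S2", "female"),
        ("X", "K1", "K2", "male"),
    ]
    return Pedigree(Individual(iid, "INB", f, m, s) for iid, f, m, s in rows)


@pytest.fixture(scope="session")
def extended_pedigree() -> Pedigree:
    return make_extended_pedigree()


@pytest.fixture(scope="session")
def inbred_pedigree() -> Pedigree:
    return make_inbred_pedigree()


@pytest.fixture(scope="session")
def sim_pedigree_200() -> Pedigree:
    """200 simulated three-generation families with all classes populated."""
    cfg = SimulationConfig(
        n_families=200,
        generations=3,
        singleton_rate=0.15,
        extension_prob=0.35,
        seed=11,
    )
    return simulate_pedigrees(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def nuclear_config(n_families: int, seed: int, **overrides) -> SimulationConfig:
    """Nuclear-family study conditions for heritability recovery runs."""
    base = dict(
        n_families=n_families,
        generations=2,
        singleton_rate=0.0,
        h2_true=0.30,
        c2_couple=0.0,
        spousal_r=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)
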