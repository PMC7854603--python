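import numpy as np
import pytest

from samlink.dntpase_census import build_profile, calibrate_evalue
from samlink.synthetic_data import GeneratorConfig, gen_family_dataset


@pytest.fixture(scope="session")
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def family_dataset(config):
    """Default synthetic two-family dataset: (sequences, chromosomes, truth)."""
    return gen_family_dataset(config)


@pytest.fixture(scope="session")
def calibrated_profiles(family_dataset):
    """Profiles built from full-length members and E-value calibrated."""
    sequences, _, truth = family_dataset
    seeds = {"family_a": [], "family_b": []}
    for s in sequences:
        if not truth["truncated"][s.protein_acc]:
            seeds[truth["labels"][s.protein_acc]].append(s.sequence)
    pa = build_profile(seeds["family_a"][:8], name="samhd1_like")
    pb = build_profile(seeds["family_b"][:8], name="dgt_like")
    calibrate_evalue(pa, n_shuffles=150, seed=11)
    calibrate_evalue(pb, n_shuffles=150, seed=12)
    return pa, pb
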