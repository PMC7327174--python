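"""Shared fixtures: small seeded synthetic genome sets with planted truth."""

import numpy as np
import pytest

from hemenet.hemescan import scan_proteome
from hemenet.synthetic import SyntheticConfig, generate_genome_set

#: study-condition-shaped but desk-scale configuration used across tests;
#: moderate heme counts keep between-family local identity well below the
#: clustering threshold, matching the planted-recovery conditions.
SMALL_KWARGS = dict(
    n_genomes=4,
    proteins_per_genome=(120, 160),
    n_families=5,
    mhc_per_genome_range=(6, 10),
    mhc_fraction=0.4,
    heme_count_range=(3, 8),
    giant_heme_count=None,
)


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    kwargs = dict(SMALL_KWARGS)
    kwargs.update(overrides)
    return SyntheticConfig(seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_set():
    return generate_genome_set(small_config())


@pytest.fixture(scope="session")
def small_scan(small_set):
    annotations, stats = scan_proteome(small_set.all_proteins())
    return annotations, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
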