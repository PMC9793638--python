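"""Shared fixtures: equilibrium ancestral populations at desk scale.

The large fixture emulates the study conditions on a configuration-scaled
genome (one 50-Mb chromosome, all per-bp rates at their defaults): N = 500
for 5000 generations under the default mutation model.  Smaller fixtures
serve structural tests that do not need an equilibrium population.
"""

import numpy as np
import pytest

from inbredsim.sim_core import EffectModel, GenomeSpec, burn_in


@pytest.fixture(scope="session")
def ancestral_pop():
    """Equilibrium N=500 population on a 50-Mb genome (default rates)."""
    genome = GenomeSpec(n_chromosomes=1, chrom_length_bp=50_000_000)
    return burn_in(genome, 500, 5000, EffectModel(), rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_ancestral():
    """Cheap non-equilibrium population for structural tests."""
    genome = GenomeSpec(n_chromosomes=2, chrom_length_bp=10_000_000)
    return burn_in(genome, 60, 200, EffectModel(), rng=np.random.default_rng(7))


@pytest.fixture
def rng():
    return np.random.default_rng(20221227)
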