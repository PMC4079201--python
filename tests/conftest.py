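import numpy as np
import pytest

import satscan as ss

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site with probability ``rate`` (always to a new base)."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic genome shared across the suite."""
    cfg = ss.SimConfig(seed=42)
    genome, rmap, truth = ss.simulate_genome(cfg)
    return cfg, genome, rmap, truth


@pytest.fixture(scope="session")
def default_profile(default_sim):
    """Focal-vs-background 13-mer profile of the default synthetic genome."""
    _, genome, _, _ = default_sim
    focal_table = ss.count_kmers(genome.focal, 13)
    background_table = ss.count_kmers(genome.background, 13)
    return ss.relative_profile(genome.focal[0], focal_table, background_table)


@pytest.fixture(scope="session")
def default_monomer(default_sim, default_profile):
    """Consensus monomer recovered from the largest called cluster."""
    _, genome, _, _ = default_sim
    clusters = ss.call_clusters(default_profile, chromosome=genome.focal[0])
    biggest = max(clusters, key=lambda c: c.length)
    period = ss.top_period(biggest.sequence)
    return ss.build_consensus(biggest.sequence, period, monomer_id="rep")


@pytest.fixture(scope="session")
def default_hits(default_sim, default_monomer):
    _, genome, _, _ = default_sim
    return ss.search(default_monomer, genome)
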