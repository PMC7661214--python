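import numpy as np
import pytest

from mitolong import pseudo_circularize, simkit


@pytest.fixture(scope="session")
def circle16k():
    """A circle of the study's mitogenome length (content irrelevant)."""
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 16666))
    return pseudo_circularize(seq, ref_id="mt16k")


@pytest.fixture(scope="session")
def small_sim():
    """A small default-condition simulated library shared across tests."""
    config = simkit.SimulationConfig(seed=11, n_reads=800)
    genomes = simkit.generate_genomes(config)
    sim = simkit.simulate_reads(config, genomes)
    return config, genomes, sim


def brute_force_fold(ref_start, ref_end, L):
    """Per-base oracle: multiset of circular positions covered by a doubled-
    reference interval."""
    return [p % L for p in range(ref_start, ref_end)]
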