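import numpy as np
import pytest

from sporoseq import simulate as sim


@pytest.fixture(scope="session")
def reference_scenario():
    """A default fragmented-reference scenario with all three event classes."""
    params = sim.RevisionScenarioParams(n_genes=80, seed=7)
    records, truth = sim.generate_reference(params)
    return params, records, truth


@pytest.fixture(scope="session")
def count_scenario():
    """A moderate count scenario with planted fold changes."""
    ids = [f"t{i:04d}" for i in range(2000)]
    params = sim.CountScenarioParams(n_transcripts=2000, frac_de=0.2, seed=9)
    counts, samples, truth = sim.generate_counts(ids, params)
    return counts, samples, truth


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
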