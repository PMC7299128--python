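import numpy as np
import pandas as pd
import pytest

from heterochron import (
    CountMatrix,
    SampleRecord,
    SimulationConfig,
    simulate_two_species,
)


def make_count_matrix(counts, phases=None, species="spX", stages=None):
    """Build a CountMatrix from a 2-D array; default samples alternate
    sporophyte stages unless phases/stages are given."""
    counts = np.asarray(counts)
    n_samples = counts.shape[1]
    if phases is None:
        phases = ["sporophyte"] * n_samples
    if stages is None:
        stages = [
            str((i % 4) + 1) if ph == "sporophyte" else "G"
            for i, ph in enumerate(phases)
        ]
    samples = [
        SampleRecord(
            sample_id=f"s{i}", species=species, phase=phases[i],
            stage=stages[i], replicate=i + 1,
        )
        for i in range(n_samples)
    ]
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes,
                     columns=[s.sample_id for s in samples]),
        samples,
    )


@pytest.fixture(scope="session")
def small_simulation():
    """200 shared orthologs + 50 species-specific genes per species."""
    cfg = SimulationConfig(
        n_shared_orthologs=200, n_specific_per_species=50, seed=11
    )
    return simulate_two_species(cfg)
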