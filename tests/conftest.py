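import pytest

from vnarscope.filtering import filter_full_length
from vnarscope.repertoire import RepertoireDataset, collapse_unique
from vnarscope.simulate import SimulationParams, SimulationResult, simulate


def build_dataset(sim: SimulationResult, library: str, annotate: bool = True) -> RepertoireDataset:
    """Filter + collapse (+ annotate) one simulated library."""
    result = filter_full_length(sim.reads[library], sim.anchors)
    ds = collapse_unique(result.sequences, library, filter_stats=result.stats)
    if annotate:
        ds.annotate()
    return ds


@pytest.fixture(scope="session")
def small_sim() -> SimulationResult:
    """A small, contaminated but sequencing-error-free library pair.

    Error-free so that filter counters and the clean clone table are exactly
    predictable from the truth records.
    """
    params = SimulationParams(
        seed=11,
        n_reads=4000,
        background_clonotypes=1200,
        sequencing_error_rate=0.0,
    )
    return simulate(params)


@pytest.fixture(scope="session")
def clean_sim() -> SimulationResult:
    """A contamination-free, error-free pair: every read passes the filter."""
    params = SimulationParams(
        seed=7,
        n_reads=3000,
        background_clonotypes=1000,
        frameshift_rate=0.0,
        stop_codon_rate=0.0,
        sequencing_error_rate=0.0,
    )
    return simulate(params)
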