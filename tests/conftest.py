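import numpy as np
import pytest

from vgwas.data import GenotypeMatrix, MarkerInfo
from vgwas.simulate import SimConfig, simulate_population


def make_genotypes(calls, accession_ids=None, chrom="1", positions=None,
                   marker_ids=None):
    """Small helper to build a GenotypeMatrix from a 0/1/nan array."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if accession_ids is None:
        accession_ids = [f"a{i}" for i in range(n)]
    if positions is None:
        positions = list(range(1, m + 1))
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(m)]
    markers = []
    for j in range(m):
        col = calls[:, j]
        obs = col[~np.isnan(col)]
        freq = obs.mean() if obs.size else 0.0
        markers.append(MarkerInfo(marker_ids[j], chrom, positions[j], "A", "C",
                                  min(freq, 1 - freq)))
    return GenotypeMatrix(accession_ids, markers, calls)


@pytest.fixture(scope="session")
def default_pop():
    """One default synthetic population, shared across tests."""
    return simulate_population(SimConfig.default(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_pop):
    from vgwas.pipeline import analyze_population

    return analyze_population(default_pop)
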