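import numpy as np
import pytest

from silkymap.genotypes import GenotypeMatrix, Individual
from silkymap.markers import MarkerMap


@pytest.fixture
def small_map() -> MarkerMap:
    """Eight markers at 10 kb spacing on one chromosome."""
    return MarkerMap.from_records(
        [(f"M{i}", "3", 70_000_000 + i * 10_000) for i in range(8)]
    )


def make_matrix(calls, phenotype="case", ids=None, populations=None,
                marker_ids=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"{phenotype}_{i}" for i in range(n)]
    phenotypes = [phenotype] * n if isinstance(phenotype, str) else phenotype
    populations = populations or [""] * n
    individuals = [Individual(i, p, q) for i, p, q in zip(ids, phenotypes, populations)]
    marker_ids = marker_ids or [f"M{j}" for j in range(m)]
    return GenotypeMatrix(individuals, marker_ids, calls)
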