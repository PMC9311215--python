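import numpy as np
import pytest

from adaptscan import GenotypeMatrix, PopulationMap


def make_dataset(geno_by_pop: dict, groups: dict | None = None, tags=None):
    """Build (GenotypeMatrix, PopulationMap) from {pop: 2-D dosage rows}.

    ``geno_by_pop[pop]`` is an (n_ind, n_loci) array-like; -1 marks missing.
    ``groups`` optionally maps population -> group (default: own group).
    """
    rows, inds, pops, grps = [], [], [], []
    for pop, arr in geno_by_pop.items():
        arr = np.asarray(arr, dtype=np.int8)
        for i, row in enumerate(arr):
            rows.append(row)
            inds.append(f"{pop}-{i}")
            pops.append(pop)
            grps.append((groups or {}).get(pop, pop))
    geno = np.stack(rows)
    n_loci = geno.shape[1]
    g = GenotypeMatrix(
        geno,
        locus_ids=np.array([f"L{j}" for j in range(n_loci)], dtype=object),
        tag_ids=np.array(
            tags if tags is not None else [f"T{j}" for j in range(n_loci)],
            dtype=object,
        ),
        individual_ids=np.array(inds, dtype=object),
    )
    pm = PopulationMap(np.array(inds, dtype=object),
                      np.array(pops, dtype=object),
                      np.array(grps, dtype=object))
    return g, pm


@pytest.fixture
def two_pop_hand_case():
    """2 populations x 4 diploids, p=0.25 vs p=0.75, explicit genotypes."""
    return {
        "A": [[1, 0], [0, 1], [1, 0], [0, 1]],   # 2 loci, alt freq 0.25 each
        "B": [[2, 1], [1, 2], [2, 1], [1, 2]],   # alt freq 0.75 each
    }
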