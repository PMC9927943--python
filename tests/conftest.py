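import numpy as np
import pandas as pd
import pytest

from dnmeth.regions import RegionCountMatrix
from dnmeth.synthetic import (
    CohortSimConfig,
    RegionSimConfig,
    simulate_annotation,
    simulate_cohort,
    simulate_region_counts,
)


@pytest.fixture(scope="session")
def small_matrix():
    cfg = RegionSimConfig(n_regions=50, n_per_group=6, baseline_mean=40,
                          dispersion=0.15, seed=11)
    matrix, _ = simulate_region_counts(cfg)
    return matrix


@pytest.fixture(scope="session")
def planted_region_data():
    cfg = RegionSimConfig(n_regions=400, n_per_group=12, baseline_mean=50,
                          dispersion=0.1, n_hypo_dmrs=45, n_hyper_dmrs=15,
                          effect_fold=2.0, seed=5)
    return simulate_region_counts(cfg)


@pytest.fixture(scope="session")
def annotation_fixture(planted_region_data):
    matrix, truth = planted_region_data
    bundle = simulate_annotation(matrix.regions, truth, n_genes=40, n_cgis=25,
                                 planted_or=3.0, seed=5)
    return matrix, truth, bundle


@pytest.fixture(scope="session")
def cohort_fixture():
    cfg = CohortSimConfig(seed=21)
    return simulate_cohort(cfg), cfg


def tiny_matrix(counts, groups, **design_extra):
    counts = np.asarray(counts)
    n = counts.shape[0]
    regions = pd.DataFrame({"chrom": "chrS", "start": np.arange(n) * 1000,
                            "end": np.arange(n) * 1000 + 500})
    design = pd.DataFrame({"group": groups, **design_extra},
                          index=[f"S{i}" for i in range(counts.shape[1])])
    return RegionCountMatrix(regions=regions, counts=counts, design=design)
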