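import numpy as np
import pytest

import ferment_rank as fr

#: coefficients of the published composite-score formula, in fixture column
#: order (TTA, Volume, Hardness, Springiness)
PUBLISHED_COEFFICIENTS = np.array([0.68, 0.93, 0.89, 0.84])

#: published per-component Cos2 weights and eigenvalues for the same four
#: indicators (component 1, component 2)
PUBLISHED_EIGENVALUES = np.array([1.45, 1.06])
PUBLISHED_COS2 = np.array(
    [
        [0.35, 0.17],  # TTA
        [0.57, 0.09],  # Volume
        [0.02, 0.81],  # Hardness
        [0.55, 0.03],  # Springiness
    ]
)


@pytest.fixture(scope="session")
def reference_table():
    """The packaged 36-strain standardized indicator table with scores."""
    return fr.load_reference_scores()


@pytest.fixture(scope="session")
def reference_pca(reference_table):
    return fr.pca_correlation(reference_table)


@pytest.fixture(scope="session")
def default_genotypes():
    """Default synthetic genotype matrix: 33 planted sites over 19 genes
    between two trios, zero missingness."""
    return fr.simulate_genotypes(fr.GenotypeSimConfig(seed=11))
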