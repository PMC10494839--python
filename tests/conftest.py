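import numpy as np
import pytest

from enteromap import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_blobs(rng):
    """Three far-separated Gaussian blobs in the plane with labels."""
    X = np.vstack([rng.normal(i * 10.0, 0.5, size=(60, 2)) for i in range(3)])
    labels = np.repeat(np.arange(3), 60)
    return X, labels


@pytest.fixture
def two_rings(rng):
    """Two concentric noisy rings — separable by density, not by medoids."""
    theta = rng.uniform(0, 2 * np.pi, 200)
    inner = np.c_[np.cos(theta[:100]), np.sin(theta[:100])]
    outer = 3.0 * np.c_[np.cos(theta[100:]), np.sin(theta[100:])]
    X = np.vstack([inner, outer]) + rng.normal(0, 0.03, (200, 2))
    return X, np.repeat([0, 1], 100)


@pytest.fixture
def toy_table():
    """A tiny genus-annotated OTU table used across preprocessing tests."""
    matrix = np.array([
        [0.2, 0.3, 0.1, 0.4],
        [0.5, 0.1, 0.2, 0.2],
        [0.25, 0.25, 0.25, 0.25],
    ])
    lineages = [
        "k__Bacteria;p__Bacteroidetes;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
        "k__Bacteria;p__Bacteroidetes;o__Bacteroidales;f__Bacteroidaceae;g__Bacteroides",
        "k__Bacteria;p__Firmicutes;o__Clostridiales;f__Ruminococcaceae;g__Ruminococcus",
        "k__Bacteria;p__Firmicutes;o__Clostridiales;f__Lachnospiraceae;g__",
    ]
    return AbundanceTable(
        sample_ids=["s1", "s2", "s3"],
        taxon_ids=["otu1", "otu2", "otu3", "otu4"],
        matrix=matrix, lineages=lineages)
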