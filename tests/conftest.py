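import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from eegpipe import CohortSpec, generate_cohort
from eegpipe.features import extract_feature_matrix


@pytest.fixture(scope="session")
def cohort20():
    """Full-width cohort (10 + 10 subjects) at reduced duration for fold tests."""
    return generate_cohort(CohortSpec(duration=20.0, seed=7))


@pytest.fixture(scope="session")
def apen_features20(cohort20):
    return extract_feature_matrix(cohort20, "apen")


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort (2 + 2 subjects, 10 s) for I/O and pipeline plumbing tests."""
    return generate_cohort(
        CohortSpec(n_patients=2, n_controls=2, duration=10.0, seed=3)
    )


def gaussian_clusters(rng, centers, n_per, sd):
    """Labelled Gaussian blobs in 2-D for classifier toys."""
    X, y = [], []
    for cx, cy, lab in centers:
        X.append(
            np.column_stack(
                [rng.normal(cx, sd, n_per), rng.normal(cy, sd, n_per)]
            )
        )
        y += [lab] * n_per
    return np.vstack(X), np.array(y)
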