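import numpy as np
import pytest

import ihcsynapse as ihc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_gt():
    """Two-synapse ground truth used across imaging/pipeline tests."""
    return ihc.sample_ground_truth(2, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_gt):
    """One rendered dual-color experiment (default noise)."""
    return ihc.render_experiment(small_gt, seed=1)


@pytest.fixture(scope="session")
def analyzed_records(small_bundle):
    return ihc.analyze_cell(small_bundle, cell_id=0)
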