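import numpy as np
import pytest

import octoscope as oc


@pytest.fixture(scope="session")
def cohort40():
    """Balanced 40-scan phantom cohort (10 per class), default noise."""
    return oc.make_cohort(10, base_seed=42)


@pytest.fixture(scope="session")
def table40(cohort40):
    scans = [s for s, _ in cohort40]
    labels = [t.label for _, t in cohort40]
    return oc.cohort_feature_table(scans, labels)


@pytest.fixture(scope="session")
def model40(table40):
    return oc.train_cascade(table40, table40["label"])


@pytest.fixture(scope="session")
def labels40(cohort40):
    return np.array([t.label for _, t in cohort40])
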