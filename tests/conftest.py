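import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orscreen as o

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel1():
    """Default synthetic training panel (seed 1): records, raw matrix,
    prepared (cleaned + scaled) matrix, labels, activity, ground truth."""
    records, matrix, truth = o.gen_training_set(o.ChemSimConfig(seed=1))
    work = o.scale_matrix(o.clean_matrix(matrix))
    labels = np.array([r.active_label == "active" for r in records])
    activity = np.array([r.activity for r in records])
    return records, matrix, work, labels, activity, truth


@pytest.fixture(scope="session")
def fitted1(panel1):
    """Subset + trained SVR on the seed-1 panel."""
    records, matrix, work, labels, activity, truth = panel1
    subset = o.sfs_select(work, labels, target_size=3)
    model = o.train(work, subset, activity)
    return subset, model


def pairs_auc(scores, positive):
    """Brute-force all-pairs AUC oracle (ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos = scores[positive]
    neg = scores[~positive]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)
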