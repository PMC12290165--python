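import numpy as np
import pytest

from nihssnet.cohort import OrdinalScoreMatrix
from nihssnet import synthdata


def make_scores(X, item_max=None, ids=None, items=None):
    """Convenience constructor for small literal score matrices."""
    X = np.asarray(X)
    n, m = X.shape
    if item_max is None:
        item_max = np.maximum(X.max(axis=0), 4)
    return OrdinalScoreMatrix(
        subject_ids=ids or [f"s{i}" for i in range(n)],
        item_names=items or [f"item{j}" for j in range(m)],
        item_max=item_max,
        X=X,
    )


def random_scores(rng, n, m, max_score=4):
    item_max = rng.integers(2, max_score + 1, size=m)
    X = rng.integers(0, item_max[None, :] + 1, size=(n, m))
    # keep the GDM defined: no subject may tie with everyone on every item
    for a in range(n):
        while np.all(np.sign(X[a] - X) == 0, axis=1).sum() == n:
            X[a] = rng.integers(0, item_max + 1, size=m)
    return make_scores(X, item_max=item_max)


@pytest.fixture(scope="session")
def default_cohort():
    """The default five-syndrome synthetic cohort (scores, volumes, truth)."""
    return synthdata.generate_cohort(seed=0)


@pytest.fixture(scope="session")
def default_similarity(default_cohort):
    from nihssnet.gdm import gdm_distance, gsm_network

    scores, _, _ = default_cohort
    return gsm_network(gdm_distance(scores))
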