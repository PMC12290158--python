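import numpy as np
import pytest

from fairpost import GroupedScores, SyntheticConfig, simulate_dataset
from fairpost.fixtures import toy_scores_frame


@pytest.fixture(scope="session")
def toy_scores() -> GroupedScores:
    """24 handcrafted instances with a known group TPR gap."""
    df = toy_scores_frame()
    return GroupedScores(score=df.score, true_label=df.y, group=df.group)


@pytest.fixture(scope="session")
def synth_ds():
    """The 2000-row class-balanced medium-separation dataset."""
    return simulate_dataset(SyntheticConfig(s=0.0, n_per_class=1000, seed=42))


@pytest.fixture(scope="session")
def logistic_split(synth_ds):
    """Logistic scores on a held-out half of the synthetic data."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(5)
    idx = rng.permutation(synth_ds.n)
    train, test = idx[:1000], idx[1000:]
    model = LogisticRegression(max_iter=1000).fit(
        synth_ds.features[train], synth_ds.labels[train]
    )
    scores = model.predict_proba(synth_ds.features[test])[:, 1]
    return GroupedScores(
        score=scores,
        true_label=synth_ds.labels[test],
        group=synth_ds.protected["A"][test],
        features=synth_ds.features[test],
    )
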