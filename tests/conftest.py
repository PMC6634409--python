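import numpy as np
import pytest

from hetmix.panel import PanelParams, generate_panel
from hetmix.prep import EXPRESSION, MUTATION, FeatureDataset

SMALL_PANEL = PanelParams(
    n_tumor_lines=10,
    n_normal_profiles=2,
    n_variants=120,
    n_genes=150,
    seed=7,
)


@pytest.fixture(scope="session")
def small_panel():
    """A down-sized panel shared by the fast unit tests."""
    return generate_panel(SMALL_PANEL)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_planted_dataset(
    n_samples=120,
    n_features=30,
    n_informative=5,
    effect=3.0,
    set_kind="E",
    noise_sd=1.0,
    seed=0,
    labels=None,
):
    """Labeled dataset where the first ``n_informative`` features carry the signal.

    Expression-type features are lognormal-ish non-negative values whose log
    scale shifts by ``effect`` standard deviations in the positive class;
    mutation-type features are Bernoulli with a class-dependent rate.
    """
    g = np.random.default_rng(seed)
    if labels is None:
        y = np.repeat([0, 1], [n_samples - n_samples // 2, n_samples // 2])
        g.shuffle(y)
    else:
        y = np.asarray(labels, dtype=int)
        n_samples = len(y)
    if set_kind == "M":
        base = g.random(n_features) * 0.2 + 0.1
        probs = np.tile(base, (n_samples, 1))
        lift = np.clip(base[:n_informative] + 0.25 * effect, 0, 0.95)
        probs[y == 1, :n_informative] = lift
        X = (g.random((n_samples, n_features)) < probs).astype(float)
        types = np.array([MUTATION] * n_features, dtype=object)
    else:
        log_x = g.normal(4.0, noise_sd, (n_samples, n_features))
        log_x[y == 1, :n_informative] += effect * noise_sd
        X = np.exp(log_x)
        types = np.array([EXPRESSION] * n_features, dtype=object)
    ids = [f"{'m' if set_kind == 'M' else 'e'}{i:03d}" for i in range(n_features)]
    return FeatureDataset(X=X, y=y, feature_ids=ids, feature_types=types, set_kind=set_kind)
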