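import numpy as np
import pytest

import avimeta as am


@pytest.fixture(scope="session")
def yule_tree():
    """A fixed 10-tip Yule tree used across tests."""
    return am.simulate_tree(10, seed=42)


@pytest.fixture(scope="session")
def yule_corr(yule_tree):
    return am.tree_to_correlation(yule_tree)


def make_effects(rng, corr, k, mu=0.0, sigma2_phylo=0.0, sigma2_study=0.0,
                 n_studies=6, seasons=("non-breeding", "breeding"), variable="PHA"):
    """Directly generate effect sizes from the meta-model's own generative story."""
    sp = list(corr.labels)
    L = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(len(sp)))
    a = np.sqrt(sigma2_phylo) * (L @ rng.standard_normal(len(sp)))
    b = np.sqrt(sigma2_study) * rng.standard_normal(n_studies)
    out = []
    for i in range(k):
        si = rng.integers(len(sp))
        st = rng.integers(n_studies)
        season = seasons[i % len(seasons)]
        v = float(rng.uniform(0.05, 0.3))
        y = mu + a[si] + b[st] + rng.normal(0.0, np.sqrt(v))
        out.append(
            am.EffectSize(g=float(y), v=v, species=sp[si], study=f"study{st}",
                          variable=variable, season=season)
        )
    return out


@pytest.fixture
def effect_factory(yule_corr):
    def factory(seed, **kwargs):
        return make_effects(np.random.default_rng(seed), yule_corr, **kwargs)

    return factory
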