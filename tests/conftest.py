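import numpy as np
import pytest

from phenofda import SceneConfig, SynthGrowthConfig, make_basis, synth_scene


@pytest.fixture(scope="session")
def clean_scene():
    """Deterministic noise-free scene: (plant, empty pot, truth mask)."""
    cfg = SceneConfig(noise_sd=0.0, plant_color_sd=0.0, seed=0)
    return synth_scene(cfg) + (cfg,)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_masks(rng, n, shape=(16, 16), p=0.4):
    return [rng.random(shape) < p for _ in range(n)]


def spline_truth_config(seed=0, **kw):
    """Growth config whose true effect curves live exactly in the default
    spline basis, so a noiseless fit can recover them without bias."""
    base = SynthGrowthConfig(sigma=0.0, retention=1.0, seed=3, **kw)
    days = np.linspace(*base.day_range, base.m_days)
    basis = make_basis(days)
    rng = np.random.default_rng(seed)

    def fun():
        c = rng.normal(size=basis.K)
        return lambda t, c=c: basis.design(np.atleast_1d(t)) @ c

    base.mu = fun()
    base.genotype_effects = [fun() for _ in range(base.n_genotypes - 1)]
    base.block_effects = [fun() for _ in range(base.n_blocks - 1)]
    return base
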