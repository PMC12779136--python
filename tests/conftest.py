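import numpy as np
import pytest

import fluxgan as fg
from fluxgan.classify import RFConfig, assemble_features, train_rf
from fluxgan.contextualize import contextualize_sample
from fluxgan.gan_augment import GANConfig, _train_scaled


@pytest.fixture(scope="session")
def toy_net():
    return fg.build_toy_network()


@pytest.fixture(scope="session")
def toy_cohort(toy_net):
    """Balanced 40/40 cohort, contextualized and classified (seed 1)."""
    m = fg.filter_zero_genes(fg.simulate_expression(toy_net, fg.PhenotypeSpec(seed=1)))
    models = [contextualize_sample(m, toy_net, s) for s in m.sample_ids]
    fm = assemble_features(models, m.labels, m.origin)
    forest, report = train_rf(fm, RFConfig(seed=1))
    return {"expr": m, "models": models, "features": fm, "forest": forest, "report": report}


@pytest.fixture(scope="session")
def trained_2gene_gan():
    """WGAN-GP trained on the frozen 2-gene Gaussian toy problem.

    Training data: 16 samples ~ N((0.3, -0.5), 0.1^2) in the scaled space.
    Shared session-wide because training runs the full 2000-epoch protocol.
    """
    rng = np.random.default_rng(1)
    data = np.array([0.3, -0.5]) + 0.1 * rng.standard_normal((16, 2))
    cfg = GANConfig(seed=0)
    gen, critic, history = _train_scaled(data, cfg)
    return {"data": data, "config": cfg, "generator": gen, "critic": critic, "history": history}
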