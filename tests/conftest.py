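import logging

import numpy as np
import pytest

from ppiforest import SyntheticConfig, generate_dataset
from ppiforest.evaluation import PipelineConfig
from ppiforest.lpp import LPPConfig

# identity-block fallbacks in degenerate bootstrap subsets are expected in
# tiny tests; keep the log quiet
logging.getLogger("ppiforest.rotation_forest").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """30 proteins, 40+40 planted pairs with a strong signal; fast."""
    cfg = SyntheticConfig(
        n_proteins=30,
        length_range=(30, 60),
        separation=4.0,
        n_pos_pairs=40,
        n_neg_pairs=40,
        seed=5,
    )
    proteins, pssms, pairs, latents = generate_dataset(cfg)
    return {
        "config": cfg,
        "proteins": proteins,
        "pssms": pssms,
        "pairs": pairs,
        "latents": latents,
    }


@pytest.fixture()
def small_pipeline_config():
    return PipelineConfig(lpp=LPPConfig(out_dim=8, n_neighbors=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
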