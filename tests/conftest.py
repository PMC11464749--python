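import numpy as np
import pytest

from qsprkit import FixtureConfig, PipelineConfig, QSPRModel, TrainingConfig
from qsprkit.fixtures import generate


@pytest.fixture(scope="session")
def small_fixture():
    """120-compound synthetic table with engineered replicate structure."""
    cfg = FixtureConfig(
        n_compounds=120, replicate_rate=0.3, inconsistent_fraction=0.2,
        noise_sd=0.2, seed=7,
    )
    raw, truth = generate(cfg)
    return cfg, raw, truth


@pytest.fixture(scope="session")
def recovery_results():
    """Tuned ridge pipeline on the 500-compound sigma=0.2 regression set.

    Session-scoped: several tests inspect different facets of one fit.
    """
    cfg = FixtureConfig(n_compounds=500, replicate_rate=0.3,
                        inconsistent_fraction=0.2, noise_sd=0.2, seed=42)
    raw, truth = generate(cfg)
    tcfg = TrainingConfig(task="regression", model_family="ridge",
                          hpo_max_evals=20, seed=42)
    pcfg = PipelineConfig()  # reference recipe: 8 descriptors + 2 flags + 50 PCs
    model = QSPRModel.from_dataframe(raw, tcfg, pcfg)
    return model.fit()
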