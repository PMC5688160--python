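import numpy as np
import pytest

from phenonet import PipelineConfig, run_pipeline
from phenonet.synthetic import SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default planted-block cohort, fixed seed, no I/O."""
    config = PipelineConfig(synthetic=SyntheticSpec(seed=1), louvain_seed=1,
                            output_dir="unused")
    return run_pipeline(config, write=False)


@pytest.fixture(scope="session")
def small_spec():
    """A smaller planted cohort for quick structural tests."""
    return SyntheticSpec(
        n_subjects=400, block_sizes=(6, 6, 6), within_block_corr=0.6,
        backbone_coupling=0.3, categorical_fraction=0.3, n_levels=3,
        missing_rate=0.05, seed=7,
    )
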