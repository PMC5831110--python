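import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import coexmeta as cm
from coexmeta.simulate import probe_map_frame

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return cm.SimConfig(
        n_batches=2, samples_per_batch=(120, 100), n_genes=300,
        module_size=10, n_outliers=2, rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_compendium(small_config):
    return cm.generate_compendium(small_config)


@pytest.fixture(scope="session")
def small_probe_map(small_compendium):
    batches, _ = small_compendium
    return probe_map_frame(batches)


@pytest.fixture(scope="session")
def fitted_meta(small_compendium, small_probe_map):
    batches, _ = small_compendium
    clean = [cm.run_batch_qc(b)[0] for b in batches]
    return cm.SeedAssociationMeta(top_k=50).fit(clean, small_probe_map)


@pytest.fixture()
def tiny_batch():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(rng.normal(8, 1, size=(20, 6)),
                        index=[f"P{i}" for i in range(20)],
                        columns=[f"S{i}" for i in range(6)])
    return cm.ExpressionBatch("T1", data)
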