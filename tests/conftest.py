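import numpy as np
import pytest
from hypothesis import settings

from pupcensus import datasets

settings.register_profile("ci", max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20170101)


@pytest.fixture()
def registry_csv(tmp_path):
    """The 21-colony registry written in the canonical CSV schema
    (plus an informational state column)."""
    path = tmp_path / "colonies.csv"
    datasets.registry_frame().to_csv(path, index=False)
    return path


@pytest.fixture()
def registry(registry_csv):
    from pupcensus import load_registry

    return load_registry(registry_csv)
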