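from __future__ import annotations

import pytest
from hypothesis import settings

from termrank import GeneratorConfig, RunConfig, generate, run

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-configuration synthetic study, seed 1 (shared, read-only)."""
    out = tmp_path_factory.mktemp("synthetic")
    return generate(GeneratorConfig(seed=1), out)


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline result on the default seed-1 synthetic study."""
    ds = default_dataset
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        network=ds.network_path,
        annotations=ds.annotations_path,
        universe=ds.universe_path,
        positives=ds.positives_path,
        out_dir=out,
    )
    return run(cfg)
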