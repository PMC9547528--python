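import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from subfrac.config import SimConfig
from subfrac.report import run_pipeline
from subfrac.synthetic import generate_dataset


def toy_config(**overrides) -> SimConfig:
    """Small two-chromosome genome (~220 ancestral genes) for fast tests."""
    defaults = dict(seed=11, chrom_length=10_000_000)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    """One shared toy dataset on disk."""
    out = tmp_path_factory.mktemp("toy_data")
    manifest = generate_dataset(toy_config(), out)
    return out, manifest


@pytest.fixture(scope="session")
def toy_pipeline(toy_dataset, tmp_path_factory):
    """Pipeline summary + output dir for the shared toy dataset."""
    data_dir, _ = toy_dataset
    out = tmp_path_factory.mktemp("toy_out")
    summary = run_pipeline(data_dir, out)
    return out, summary
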