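import numpy as np
import pytest

from duostream.model import fast_spec
from duostream.preprocess import PreprocessConfig
from duostream.synthetic_data import SynthSpec, generate_dataset
from duostream.training import fast_schedules, run_single_experiment


@pytest.fixture(scope="session")
def synth_spec():
    """The desk-scale study conditions: 6 classes x 20 pairs, 64px, overlap 2/3."""
    return SynthSpec()


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory, synth_spec):
    d = tmp_path_factory.mktemp("synth")
    generate_dataset(synth_spec, d)
    return d


@pytest.fixture(scope="session")
def synth_manifest(synth_dir):
    from duostream.datasets import read_manifest

    return read_manifest(synth_dir / "manifest.csv")


@pytest.fixture(scope="session")
def small_synth_manifest(tmp_path_factory):
    """A smaller dataset (6 classes x 6 pairs, 48px) for machinery tests."""
    d = tmp_path_factory.mktemp("synth_small")
    spec = SynthSpec(pairs_per_class=6, image_size=48)
    generate_dataset(spec, d)
    from duostream.datasets import read_manifest

    return read_manifest(d / "manifest.csv")


@pytest.fixture(scope="session")
def fast_cfg():
    return PreprocessConfig(target_size=32)


@pytest.fixture(scope="session")
def preprocess_cache():
    return {}


@pytest.fixture(scope="session")
def trained_model(synth_manifest, fast_cfg, preprocess_cache):
    """One staged training run of the full two-stream model (seed 1)."""
    model, report, history = run_single_experiment(
        synth_manifest, fast_spec(6), fast_cfg, fast_schedules(), seed=1,
        cache=preprocess_cache,
    )
    return model, report, history


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
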