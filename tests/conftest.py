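import numpy as np
import pytest

from qrsnet import (
    NetworkSpec,
    QRSDetector,
    SynthConfig,
    TrainConfig,
    generate_record,
    make_training_corpus,
    train,
)
from qrsnet.records import RecordBundle
from qrsnet.synth import heldout_records


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Noise- and wander-free 60 s record at the MLII convention."""
    return SynthConfig(duration=60.0, mean_hr=60.0, hr_jitter=0.05)


@pytest.fixture(scope="session")
def clean_record(clean_config):
    signal, annotations = generate_record(clean_config, seed=11)
    return RecordBundle(signal=signal, annotations=annotations, source_format="synthetic")


@pytest.fixture(scope="session")
def trained_detector(clean_config):
    """Detector trained once per session under the study conditions:
    a balanced corpus of 400 beats, seed 7, default regimen."""
    dataset = make_training_corpus(clean_config, n_qrs=400, seed=7)
    spec = NetworkSpec()
    result = train(dataset, spec, TrainConfig(seed=7))
    return QRSDetector(spec=spec, params=result.params)


@pytest.fixture(scope="session")
def heldout_bundles(clean_config):
    """Ten clean annotated 60 s records disjoint from the training corpus."""
    return heldout_records(clean_config, 10, seed=7)
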