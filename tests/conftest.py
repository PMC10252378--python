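import warnings

import numpy as np
import pytest

from drivestress import nets, synth
from drivestress.pipeline import PipelineConfig, segment_cohort


@pytest.fixture(scope="session")
def desk_protocol():
    return synth.DriveProtocol.standard(scale=0.1)


@pytest.fixture(scope="session")
def raw_two_class_segments(desk_protocol):
    """The same cohort as two_class_segments, before per-channel rescaling."""
    recs = synth.generate_cohort(3, desk_protocol, seed=42, separation=1.25)
    cfg = PipelineConfig(out_dir="unused", scheme="two", clean=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment_cohort(recs, cfg)


@pytest.fixture(scope="session")
def two_class_segments(desk_protocol):
    """Small cleaned two-class window set pooled from a 3-drive cohort."""
    # separation 1.25 realizes the 5-sigma class-mean gap study condition;
    # windows are segmented raw and then min-max rescaled per channel
    recs = synth.generate_cohort(3, desk_protocol, seed=42, separation=1.25)
    cfg = PipelineConfig(out_dir="unused", scheme="two", clean=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected Nyquist-clipping warnings
        return segment_cohort(recs, cfg).normalized()


@pytest.fixture(scope="session")
def three_class_segments(desk_protocol):
    recs = synth.generate_cohort(3, desk_protocol, seed=43, separation=1.25)
    cfg = PipelineConfig(out_dir="unused", scheme="three", clean=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return segment_cohort(recs, cfg).normalized()


@pytest.fixture(scope="session")
def fitted_cnn(two_class_segments):
    """One trained plain CNN shared by the read-only prediction tests."""
    spec = nets.build_cnn("srad", 2)
    opts = nets.TrainingOptions(epochs=8, minibatch=20, seed=7)
    return nets.train(spec, two_class_segments, opts)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
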