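import numpy as np
import pytest

from cmcpipe.localize import HeadModel
from cmcpipe.recording import make_default_montage


@pytest.fixture(scope="session")
def montage():
    return make_default_montage()


@pytest.fixture(scope="session")
def head_model():
    return HeadModel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def session_90s():
    """One shared 90 s planted-coupling session (kappa=2 at 20 Hz)."""
    from cmcpipe.synth import SynthConfig, gen_session

    cfg = SynthConfig(duration_s=90.0, seed=7)
    return gen_session(cfg)


@pytest.fixture(scope="session")
def preprocessed_90s(session_90s, montage):
    """Beta-filtered, 60 Hz, ICA-cleaned version of the shared session."""
    from cmcpipe import preprocess
    from cmcpipe.preprocess import ArtifactICA, FilterSpec

    rec, truth = session_90s
    spec = FilterSpec("bandpass", 4, (13.0, 30.0))
    eeg = preprocess.downsample(preprocess.bandpass(rec.pick("EEG"), spec), 60.0)
    emg = preprocess.downsample(preprocess.bandpass(rec.pick("EMG"), spec), 60.0)
    ica = ArtifactICA(random_state=7).fit(eeg, montage)
    return ica.transform(eeg), emg, truth
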