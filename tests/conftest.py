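import numpy as np
import pytest

from neurocog.recording import CHANNELS_1020, EEGRecording, EpochSet


def make_recording(
    data: np.ndarray,
    sample_rate: float = 256.0,
    phase: str = "REC",
    eogv: np.ndarray | None = None,
    eogh: np.ndarray | None = None,
    ecg: np.ndarray | None = None,
) -> EEGRecording:
    """Wrap a (19, n) array into a recording with zero auxiliaries by default."""
    n = data.shape[1]
    zeros = np.zeros(n)
    return EEGRecording(
        channel_labels=CHANNELS_1020,
        sample_rate=sample_rate,
        data=data,
        aux={
            "EOGv": eogv if eogv is not None else zeros.copy(),
            "EOGh": eogh if eogh is not None else zeros.copy(),
            "ECG": ecg if ecg is not None else zeros.copy(),
        },
        phase=phase,
    )


def make_epochs(
    epochs: np.ndarray, sample_rate: float = 128.0, phase: str = "ENC"
) -> EpochSet:
    """Wrap a (n_epochs, 19, n_samples) array into an EpochSet."""
    n_ep = epochs.shape[0]
    return EpochSet(
        epochs=epochs,
        epoch_start_times=np.arange(n_ep, dtype=float),
        artifact_mask=np.zeros(n_ep, dtype=bool),
        channel_labels=CHANNELS_1020,
        sample_rate=sample_rate,
        phase=phase,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
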