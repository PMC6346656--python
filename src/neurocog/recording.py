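"""Core containers for multichannel EEG and its epoched form.

An :class:`EEGRecording` holds the 19-channel 10-20 scalp montage in
microvolts together with the EOG/ECG auxiliary traces recorded in parallel.
The paradigm has two 30-s phases: eyes-closed rest (``REC``) and a
visual-verbal memory-encoding task (``ENC``).

On disk a recording is a plain CSV matrix, one column per channel with a
channel-label header (auxiliaries named ``EOGv``, ``EOGh``, ``ECG``) and a
comment-style first line carrying the sample rate, phase and subject id.
EDF files can be read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidPhaseError, TableValidationError

#: The 19 scalp electrodes of the international 10-20 montage, in recording order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: Auxiliary channels: vertical/horizontal electro-oculogram and wrist ECG.
AUX_CHANNELS: tuple[str, ...] = ("EOGv", "EOGh", "ECG")

PHASES: tuple[str, ...] = ("REC", "ENC")


def check_phase(phase: str) -> str:
    if phase not in PHASES:
        raise InvalidPhaseError(
            f"phase must be one of {PHASES}, got {phase!r}"
        )
    return phase


@dataclass
class EEGRecording:
    """A raw or preprocessed multichannel EEG recording.

    Parameters
    ----------
    channel_labels
        Ordered scalp channel names; must be exactly the 10-20 set.
    sample_rate
        Sampling frequency in Hz (256 as recorded, 128 after downsampling).
    data
        Array of shape (n_channels, n_samples), in microvolts.
    aux
        Mapping with keys ``EOGv``, ``EOGh``, ``ECG`` to 1-D traces of the
        same length as ``data``.
    phase
        ``"REC"`` (rest, eyes closed) or ``"ENC"`` (memory encoding).
    subject_id
        Free-form subject identifier.
    """

    channel_labels: tuple[str, ...]
    sample_rate: float
    data: np.ndarray
    aux: dict[str, np.ndarray]
    phase: str
    subject_id: str = "S000"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if sorted(self.channel_labels) != sorted(CHANNELS_1020):
            missing = set(CHANNELS_1020) - set(self.channel_labels)
            extra = set(self.channel_labels) - set(CHANNELS_1020)
            raise TableValidationError(
                f"channel labels must be the 10-20 set exactly once; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        check_phase(self.phase)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise TableValidationError(
                f"data must be (n_channels={len(self.channel_labels)}, n_samples), "
                f"got {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise TableValidationError("EEG data contains non-finite values")
        for name, trace in self.aux.items():
            trace = np.asarray(trace, dtype=float)
            if trace.shape != (self.n_samples,):
                raise TableValidationError(
                    f"aux channel {name!r} has length {trace.shape}, "
                    f"expected ({self.n_samples},)"
                )
            self.aux[name] = trace

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy_with(self, **kwargs) -> "EEGRecording":
        new = replace(
            self,
            data=kwargs.pop("data", self.data).copy(),
            aux={k: v.copy() for k, v in kwargs.pop("aux", self.aux).items()},
            history=list(self.history),
            **kwargs,
        )
        return new

    def log(self, step: str) -> None:
        self.history.append(step)


@dataclass
class EpochSet:
    """Overlapping fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch);
    ``artifact_mask`` is True where the epoch is rejected.  Masked epochs
    are retained for audit and excluded from every downstream average.
    """

    epochs: np.ndarray
    epoch_start_times: np.ndarray
    artifact_mask: np.ndarray
    channel_labels: tuple[str, ...]
    sample_rate: float
    phase: str
    subject_id: str = "S000"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.epoch_start_times = np.asarray(self.epoch_start_times, dtype=float)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.n_epochs,):
            raise TableValidationError(
                "artifact mask length must equal epoch count"
            )
        if self.epoch_start_times.shape != (self.n_epochs,):
            raise TableValidationError(
                "epoch_start_times length must equal epoch count"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_clean(self) -> int:
        return int((~self.artifact_mask).sum())

    def clean_epochs(self) -> np.ndarray:
        """Return only unmasked epochs, shape (n_clean, n_channels, n_samples)."""
        return self.epochs[~self.artifact_mask]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


# ---------------------------------------------------------------------------
# Disk formats


def write_csv(rec: EEGRecording, path) -> None:
    """Write a recording as a CSV matrix with a channel-label header.

    The first line is a ``#``-prefixed metadata record
    (``# sample_rate=256 phase=REC subject=S000``); the second line the
    column labels (19 scalp channels then EOGv, EOGh, ECG); then one row
    per sample, values in microvolts.
    """
    labels = list(rec.channel_labels) + [a for a in AUX_CHANNELS if a in rec.aux]
    mat = np.vstack(
        [rec.data] + [rec.aux[a] for a in AUX_CHANNELS if a in rec.aux]
    ).T
    with open(path, "w") as fh:
        fh.write(
            f"# sample_rate={rec.sample_rate:g} phase={rec.phase} "
            f"subject={rec.subject_id}\n"
        )
        fh.write(",".join(labels) + "\n")
        np.savetxt(fh, mat, delimiter=",", fmt="%.6f")


def read_csv(path) -> EEGRecording:
    """Read a recording written by :func:`write_csv`."""
    with open(path) as fh:
        meta_line = fh.readline().strip()
        header = fh.readline().strip().split(",")
        mat = np.loadtxt(fh, delimiter=",")
    meta = dict(
        item.split("=", 1) for item in meta_line.lstrip("# ").split() if "=" in item
    )
    if "sample_rate" not in meta:
        raise TableValidationError(f"{path}: missing sample_rate metadata line")
    scalp = [ch for ch in header if ch in CHANNELS_1020]
    aux = {ch: mat[:, header.index(ch)] for ch in header if ch in AUX_CHANNELS}
    data = mat[:, [header.index(ch) for ch in scalp]].T
    return EEGRecording(
        channel_labels=tuple(scalp),
        sample_rate=float(meta["sample_rate"]),
        data=data,
        aux=aux,
        phase=meta.get("phase", "REC"),
        subject_id=meta.get("subject", "S000"),
    )


def read_edf(path, phase: str = "REC", subject_id: str = "S000") -> EEGRecording:
    """Read an EDF recording through mne (optional dependency).

    Channel names are matched case-insensitively against the 10-20 montage;
    EOG/ECG auxiliaries are matched by the usual label prefixes.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {name.lower(): i for i, name in enumerate(raw.ch_names)}
    data_v = raw.get_data() * 1e6  # mne returns volts
    scalp_idx, labels = [], []
    for ch in CHANNELS_1020:
        if ch.lower() not in names:
            raise TableValidationError(f"{path}: missing channel {ch}")
        scalp_idx.append(names[ch.lower()])
        labels.append(ch)
    aux = {}
    for aux_name, prefixes in (
        ("EOGv", ("eogv", "veog", "eog1")),
        ("EOGh", ("eogh", "heog", "eog2")),
        ("ECG", ("ecg", "ekg")),
    ):
        for name, i in names.items():
            if name.startswith(prefixes):
                aux[aux_name] = data_v[i]
                break
    n = data_v.shape[1]
    aux = {k: v for k, v in aux.items()}
    for k in list(aux):
        aux[k] = aux[k][:n]
    return EEGRecording(
        channel_labels=tuple(labels),
        sample_rate=float(raw.info["sfreq"]),
        data=data_v[scalp_idx],
        aux=aux,
        phase=phase,
        subject_id=subject_id,
    )
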