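"""EEG preprocessing: resample, filter, remove EOG/ECG artifacts, epoch, reject.

The chain turns a raw 256-Hz recording into clean, artifact-masked 2-s
epochs at 128 Hz:

1. downsample to 128 Hz and bandpass 1-30 Hz (linear-phase FIR, >= 60 dB
   stopband, applied forward-backward so the net phase is zero);
2. remove ocular artifacts by ICA with EOG-guided component selection:
   independent components whose absolute correlation with either EOG
   reference exceeds a threshold are zeroed before reconstruction;
3. correct cardiac artifacts: R-peaks are detected on the ECG auxiliary by
   the Pan-Tompkins chain (bandpass, derivative, squaring, moving-window
   integration, adaptive threshold) and a per-channel mean cardiac template
   is subtracted around each beat;
4. cut 2-s epochs with 1-s overlap;
5. flag epochs exceeding an amplitude or sample-to-sample gradient
   threshold. Flagged epochs are masked, never deleted.

The fixed chain order (filter, EOG, ECG, epoch, reject) is recorded in each
object's history so every downstream number is traceable to its parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import AllEpochsRejectedError, RecordingTooShortError
from .recording import EEGRecording, EpochSet


@dataclass
class PreprocessingConfig:
    target_rate: float = 128.0
    band: tuple[float, float] = (1.0, 30.0)
    transition_hz: float = 0.5
    stopband_db: float = 60.0
    eog_corr_threshold: float = 0.7
    ica_seed: int = 0
    epoch_length_s: float = 2.0
    epoch_overlap_s: float = 1.0
    amplitude_threshold_uv: float = 100.0
    gradient_threshold_uv: float = 50.0


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(
    fs: float,
    band: tuple[float, float] = (1.0, 30.0),
    transition_hz: float = 0.5,
    stopband_db: float = 60.0,
) -> np.ndarray:
    """Odd-length (type 1) linear-phase FIR bandpass via a Kaiser window."""
    numtaps, beta = signal.kaiserord(stopband_db, transition_hz / (0.5 * fs))
    numtaps |= 1  # force odd length: symmetric type 1 FIR
    return signal.firwin(
        numtaps, band, window=("kaiser", beta), pass_zero=False, fs=fs
    )


def resample_and_filter(
    rec: EEGRecording, config: PreprocessingConfig | None = None
) -> EEGRecording:
    """Downsample 256 -> 128 Hz and bandpass 1-30 Hz with zero-phase FIR.

    EOG auxiliaries receive the identical treatment; the ECG auxiliary is
    only resampled (its QRS morphology must survive for beat detection).
    """
    cfg = config or PreprocessingConfig()
    if rec.sample_rate == cfg.target_rate:
        data = rec.data.copy()
        aux = {k: v.copy() for k, v in rec.aux.items()}
    else:
        factor = rec.sample_rate / cfg.target_rate
        if abs(factor - round(factor)) > 1e-9:
            raise RecordingTooShortError(
                f"sample rate {rec.sample_rate} is not an integer multiple of "
                f"{cfg.target_rate}"
            )
        q = int(round(factor))
        data = signal.resample_poly(rec.data, 1, q, axis=-1)
        aux = {k: signal.resample_poly(v, 1, q) for k, v in rec.aux.items()}

    taps = design_bandpass(cfg.target_rate, cfg.band, cfg.transition_hz, cfg.stopband_db)
    if data.shape[-1] <= 3 * len(taps):
        raise RecordingTooShortError(
            f"recording of {data.shape[-1]} samples is shorter than the filter "
            f"transient ({3 * len(taps)} samples)"
        )
    data = signal.filtfilt(taps, [1.0], data, axis=-1)
    for k in ("EOGv", "EOGh"):
        if k in aux:
            aux[k] = signal.filtfilt(taps, [1.0], aux[k])

    out = EEGRecording(
        channel_labels=rec.channel_labels,
        sample_rate=cfg.target_rate,
        data=data,
        aux=aux,
        phase=rec.phase,
        subject_id=rec.subject_id,
        history=list(rec.history),
    )
    out.log(
        f"resample_and_filter target={cfg.target_rate}Hz band={cfg.band} "
        f"taps={len(taps)} stopband={cfg.stopband_db}dB zero-phase"
    )
    return out


# ---------------------------------------------------------------------------
# ocular artifacts


def remove_eog(
    rec: EEGRecording, config: PreprocessingConfig | None = None
) -> EEGRecording:
    """ICA decomposition with EOG-correlation-gated component removal.

    Components are selected against the EOG references: any independent
    component with |r| above the threshold versus either EOG channel is
    zeroed before reconstruction. A flat or absent EOG falls back to a
    logged no-op.
    """
    cfg = config or PreprocessingConfig()
    refs = [rec.aux[k] for k in ("EOGv", "EOGh") if k in rec.aux]
    refs = [r for r in refs if np.ptp(r) > 1e-12 and r.std() > 1e-12]
    out = rec.copy_with()
    if not refs:
        warnings.warn("EOG references flat or absent; EOG removal skipped")
        out.log("remove_eog skipped: no usable EOG reference")
        return out

    from sklearn.decomposition import FastICA

    X = rec.data.T  # samples x channels
    ica = FastICA(
        n_components=rec.n_channels,
        whiten="unit-variance",
        random_state=cfg.ica_seed,
        max_iter=1000,
        tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # FastICA convergence chatter
        sources = ica.fit_transform(X)  # samples x components

    removed = []
    for k in range(sources.shape[1]):
        s = sources[:, k]
        if s.std() == 0:
            continue
        corrs = [abs(np.corrcoef(s, r)[0, 1]) for r in refs]
        if max(corrs) > cfg.eog_corr_threshold:
            removed.append(k)
    if removed:
        sources[:, removed] = 0.0
        cleaned = ica.inverse_transform(sources).T
        out.data = cleaned
    out.log(
        f"remove_eog threshold={cfg.eog_corr_threshold} "
        f"removed_components={removed}"
    )
    return out


# ---------------------------------------------------------------------------
# cardiac artifacts


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection; returns R-peak sample indices.

    Chain: 5-15 Hz bandpass, differentiation, squaring, 150-ms
    moving-window integration, then peak picking with a 250-ms refractory
    period and a threshold adapted to the integrated-signal peak heights.
    """
    ecg = np.asarray(ecg, dtype=float)
    if np.ptp(ecg) == 0:
        return np.array([], dtype=int)
    nyq = fs / 2
    b, a = signal.butter(2, [5 / nyq, min(15 / nyq, 0.99)], btype="band")
    filt = signal.filtfilt(b, a, ecg)
    deriv = np.gradient(filt)
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    distance = max(int(round(0.25 * fs)), 1)
    cand, props = signal.find_peaks(mwi, distance=distance)
    if cand.size == 0:
        return np.array([], dtype=int)
    heights = mwi[cand]
    thr = 0.3 * np.median(heights[heights >= np.median(heights)])
    cand = cand[heights > thr]

    # refine each detection to the local |filtered ECG| maximum
    half = int(round(0.10 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(ecg))
        peaks.append(lo + int(np.argmax(np.abs(filt[lo:hi]))))
    peaks = np.unique(peaks)
    # enforce refractory period after refinement
    keep = [int(peaks[0])] if peaks.size else []
    for p in peaks[1:]:
        if p - keep[-1] >= distance:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def remove_ecg(
    rec: EEGRecording,
    config: PreprocessingConfig | None = None,
    template_window_s: tuple[float, float] = (-0.15, 0.15),
) -> EEGRecording:
    """Subtract the mean cardiac template around each detected R-peak.

    For every channel, the average waveform across all beats (within the
    template window) is estimated and subtracted at each beat, which removes
    the phase-locked cardiac-field artifact while leaving non-locked EEG
    untouched in expectation. No detectable beats falls back to a warned
    no-op.
    """
    cfg = config or PreprocessingConfig()
    out = rec.copy_with()
    ecg = rec.aux.get("ECG")
    if ecg is None or np.ptp(ecg) == 0:
        warnings.warn("ECG auxiliary flat or absent; cardiac correction skipped")
        out.log("remove_ecg skipped: no usable ECG")
        return out
    peaks = detect_r_peaks(ecg, rec.sample_rate)
    if peaks.size == 0:
        warnings.warn("no detectable heartbeats; cardiac correction skipped")
        out.log("remove_ecg skipped: no beats detected")
        return out

    pre = int(round(-template_window_s[0] * rec.sample_rate))
    post = int(round(template_window_s[1] * rec.sample_rate))
    usable = peaks[(peaks >= pre) & (peaks + post < rec.n_samples)]
    if usable.size:
        segs = np.stack([rec.data[:, p - pre : p + post] for p in usable])
        template = segs.mean(axis=0)  # channels x window
        template = template - template.mean(axis=1, keepdims=True)
        for p in usable:
            out.data[:, p - pre : p + post] -= template
    out.log(
        f"remove_ecg beats={peaks.size} window={template_window_s} "
        f"template_subtraction"
    )
    return out


# ---------------------------------------------------------------------------
# epoching and rejection


def epoch(
    rec: EEGRecording, length_s: float = 2.0, overlap_s: float = 1.0
) -> EpochSet:
    """Cut fixed-length overlapping epochs; trailing partial data is dropped."""
    step_s = length_s - overlap_s
    if step_s <= 0:
        raise ValueError("overlap must be smaller than epoch length")
    n_len = int(round(length_s * rec.sample_rate))
    n_step = int(round(step_s * rec.sample_rate))
    n_total = rec.n_samples
    n_epochs = (n_total - n_len) // n_step + 1 if n_total >= n_len else 0
    if n_epochs > 0:
        starts = np.arange(n_epochs) * n_step
        epochs = np.stack([rec.data[:, s : s + n_len] for s in starts])
        start_times = starts / rec.sample_rate
    else:
        epochs = np.zeros((0, rec.n_channels, n_len))
        start_times = np.zeros(0)
    es = EpochSet(
        epochs=epochs,
        epoch_start_times=start_times,
        artifact_mask=np.zeros(n_epochs, dtype=bool),
        channel_labels=rec.channel_labels,
        sample_rate=rec.sample_rate,
        phase=rec.phase,
        subject_id=rec.subject_id,
        history=list(rec.history),
    )
    es.history.append(f"epoch length={length_s}s overlap={overlap_s}s n={n_epochs}")
    return es


def reject_artifacts(
    es: EpochSet,
    amplitude_threshold_uv: float = 100.0,
    gradient_threshold_uv: float = 50.0,
) -> EpochSet:
    """Flag epochs exceeding absolute-amplitude or gradient thresholds.

    Flagged epochs stay in the set with ``artifact_mask`` True (audit
    trail); if every epoch ends up flagged the recording is unusable and a
    named error tells the caller so.
    """
    amp = np.abs(es.epochs).max(axis=(1, 2))
    grad = (
        np.abs(np.diff(es.epochs, axis=-1)).max(axis=(1, 2))
        if es.epochs.shape[-1] > 1
        else np.zeros(es.n_epochs)
    )
    flagged = (amp > amplitude_threshold_uv) | (grad > gradient_threshold_uv)
    mask = es.artifact_mask | flagged
    if es.n_epochs > 0 and mask.all():
        raise AllEpochsRejectedError(
            "every epoch exceeds the artifact thresholds; recording unusable"
        )
    out = EpochSet(
        epochs=es.epochs.copy(),
        epoch_start_times=es.epoch_start_times.copy(),
        artifact_mask=mask,
        channel_labels=es.channel_labels,
        sample_rate=es.sample_rate,
        phase=es.phase,
        subject_id=es.subject_id,
        history=list(es.history),
    )
    out.history.append(
        f"reject_artifacts amp>{amplitude_threshold_uv}uV "
        f"grad>{gradient_threshold_uv}uV flagged={int(flagged.sum())}"
    )
    return out


def preprocess(
    rec: EEGRecording, config: PreprocessingConfig | None = None
) -> EpochSet:
    """Full chain: filter -> EOG -> ECG -> epoch -> reject."""
    cfg = config or PreprocessingConfig()
    rec = resample_and_filter(rec, cfg)
    rec = remove_eog(rec, cfg)
    rec = remove_ecg(rec, cfg)
    es = epoch(rec, cfg.epoch_length_s, cfg.epoch_overlap_s)
    return reject_artifacts(
        es, cfg.amplitude_threshold_uv, cfg.gradient_threshold_uv
    )
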