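"""The 12 EEG markers: IAF, individualized band powers, aMI, coherence, cMI.

The marker set characterizes the resting posterior rhythm and the
task-related oscillatory, information-processing and coupling properties of
the EEG:

* **Individual alpha frequency (IAF)** — spectral center of gravity between
  8 and 13 Hz on the posterior channels (P3, Pz, P4, O1, O2) at rest. The
  IAF anchors all band edges, so slowing of the dominant rhythm does not
  smear band powers across fixed canonical bands.
* **Six relative band powers** (delta ... beta2) in IAF-anchored bands
  (delta = IAF-7..IAF-5 Hz up to beta2 = IAF+8..IAF+16 Hz) on
  F3, F4, C3, C4, O1, O2 during memory encoding.
* **Auto-mutual information (aMI)** — temporal self-similarity of each
  channel, averaged over lags of 1-32 samples.
* **Inter/intrahemispheric coherence** — magnitude-squared coherence
  averaged over 1-30 Hz on fixed homologous/within-hemisphere pairs.
* **Inter/intrahemispheric cross-mutual information (cMI)** — the nonlinear
  zero-lag counterpart on the same pairs.

All markers are computed per epoch (and channel or pair), then averaged over
the unmasked epochs and the marker's channel/pair set into one global value
per subject and phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

from .errors import (
    ConfigError,
    DegenerateSpectrumError,
    InsufficientEpochsError,
    NoUnmaskedEpochsError,
)
from .information import (
    binned_mutual_information,
    lagged_auto_information,
)
from .recording import EpochSet

#: Canonical order of the 12 EEG marker columns.
EEG_MARKER_NAMES: tuple[str, ...] = (
    "iaf",
    "power_delta",
    "power_theta",
    "power_alpha1",
    "power_alpha2",
    "power_beta1",
    "power_beta2",
    "ami",
    "coherence_inter",
    "coherence_intra",
    "cmi_inter",
    "cmi_intra",
)

BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2")

#: Band edges as offsets from the anchor IAF; the six bands tile
#: [IAF-7, IAF+16] without gaps.
BAND_OFFSETS: dict[str, tuple[float, float]] = {
    "delta": (-7.0, -5.0),
    "theta": (-5.0, -2.0),
    "alpha1": (-2.0, 0.0),
    "alpha2": (0.0, 2.0),
    "beta1": (2.0, 8.0),
    "beta2": (8.0, 16.0),
}

POSTERIOR_CHANNELS: tuple[str, ...] = ("P3", "Pz", "P4", "O1", "O2")
MARKER_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "O1", "O2")
INTER_PAIRS: tuple[tuple[str, str], ...] = (("F3", "F4"), ("C3", "C4"), ("O1", "O2"))
INTRA_PAIRS: tuple[tuple[str, str], ...] = (
    ("F3", "C3"),
    ("F3", "O1"),
    ("C3", "O1"),
    ("F4", "C4"),
    ("F4", "O2"),
    ("C4", "O2"),
)

IAF_RANGE: tuple[float, float] = (8.0, 13.0)


@dataclass
class MarkerConfig:
    """Estimator constants, exposed because the exact published constants
    are not fixed by the study protocol; these defaults are the package's
    documented stand-ins."""

    n_bins: int = 16  # equiprobable histogram bins for MI
    ami_lags: tuple[int, int] = (1, 32)  # samples, inclusive
    coherence_range: tuple[float, float] = (1.0, 30.0)  # Hz
    power_denominator: str = "six_band_union"  # or "fixed_1_30"


@dataclass
class BandDefinition:
    name: str
    lo: float
    hi: float
    anchor: float  # the IAF this band was derived from

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ConfigError(f"band {self.name}: lo must be < hi")


@dataclass
class SpectralEstimate:
    """Per-epoch Hann periodograms, power in uV^2/Hz on a 0.5-Hz grid."""

    frequencies: np.ndarray  # (n_freqs,)
    power: np.ndarray  # (n_epochs, n_channels, n_freqs)
    channel_labels: tuple[str, ...]
    phase: str

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class MarkerVector:
    """Global per-subject EEG markers plus the epoch counts used."""

    iaf: float
    band_powers: dict[str, float]
    ami: float
    coherence_inter: float
    coherence_intra: float
    cmi_inter: float
    cmi_intra: float
    n_epochs_rec: int = 0
    n_epochs_enc: int = 0
    subject_id: str = "S000"

    def to_dict(self) -> dict[str, float]:
        out = {"iaf": self.iaf}
        for b in BAND_NAMES:
            out[f"power_{b}"] = self.band_powers[b]
        out.update(
            ami=self.ami,
            coherence_inter=self.coherence_inter,
            coherence_intra=self.coherence_intra,
            cmi_inter=self.cmi_inter,
            cmi_intra=self.cmi_intra,
        )
        return out


# ---------------------------------------------------------------------------
# spectral backend


def estimate_spectrum(es: EpochSet) -> SpectralEstimate:
    """Hann-tapered periodogram of every unmasked 2-s epoch.

    256-sample epochs at 128 Hz give a 0.5-Hz frequency resolution; power is
    one-sided density (uV^2/Hz), so integrating over frequency recovers the
    signal variance (Parseval).
    """
    clean = es.clean_epochs()
    if clean.shape[0] == 0:
        raise NoUnmaskedEpochsError("no unmasked epochs to estimate a spectrum from")
    freqs, power = periodogram(
        clean, fs=es.sample_rate, window="hann", scaling="density",
        detrend=False, axis=-1,
    )
    return SpectralEstimate(
        frequencies=freqs,
        power=power,
        channel_labels=tuple(es.channel_labels),
        phase=es.phase,
    )


def compute_iaf(
    spec: SpectralEstimate,
    channels: tuple[str, ...] = POSTERIOR_CHANNELS,
) -> float:
    """Individual alpha frequency: spectral center of gravity over 8-13 Hz.

    The centroid is evaluated per epoch and channel, then averaged over the
    posterior channel set; the result always lies within [8, 13] Hz.
    """
    lo, hi = IAF_RANGE
    sel = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    f = spec.frequencies[sel]
    idx = [spec.channel_index(ch) for ch in channels]
    p = spec.power[:, idx, :][:, :, sel]  # (epoch, channel, freq)
    totals = p.sum(axis=-1)
    if not (totals > 0).any():
        raise DegenerateSpectrumError("zero power in the 8-13 Hz alpha range")
    with np.errstate(invalid="ignore"):
        centroids = (p * f).sum(axis=-1) / totals
    return float(np.nanmean(centroids))


def band_edges(iaf: float) -> tuple[BandDefinition, ...]:
    """The six IAF-anchored bands; exact offset arithmetic, gap-free tiling."""
    if not IAF_RANGE[0] <= iaf <= IAF_RANGE[1]:
        raise ConfigError(f"IAF {iaf:.2f} Hz outside the admissible range [8, 13]")
    return tuple(
        BandDefinition(name, iaf + lo, iaf + hi, iaf)
        for name, (lo, hi) in BAND_OFFSETS.items()
    )


def relative_band_power(
    spec: SpectralEstimate,
    bands: tuple[BandDefinition, ...],
    channels: tuple[str, ...] = MARKER_CHANNELS,
    denominator: str = "six_band_union",
) -> dict[str, float]:
    """Relative power in each individualized band.

    Per epoch and channel, the power integrated over [lo, hi) of each band is
    divided by the power over the union of the six bands (default) or over a
    fixed 1-30 Hz range; fractions are then averaged over epochs and the
    channel set. With the default denominator the six values sum to 1 for
    every epoch/channel before averaging, hence also after.
    """
    idx = [spec.channel_index(ch) for ch in channels]
    p = spec.power[:, idx, :]
    band_power = {}
    for b in bands:
        sel = (spec.frequencies >= b.lo) & (spec.frequencies < b.hi)
        band_power[b.name] = p[:, :, sel].sum(axis=-1) * spec.df
    if denominator == "six_band_union":
        total = sum(band_power.values())
    elif denominator == "fixed_1_30":
        sel = (spec.frequencies >= 1.0) & (spec.frequencies < 30.0)
        total = p[:, :, sel].sum(axis=-1) * spec.df
    else:
        raise ConfigError(f"unknown power denominator {denominator!r}")
    if not (total > 0).any():
        raise DegenerateSpectrumError("zero total spectral power in the band union")
    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            name: float(np.nanmean(np.where(total > 0, bp / total, np.nan)))
            for name, bp in band_power.items()
        }


# ---------------------------------------------------------------------------
# information-theoretic markers


def auto_mutual_information(
    es: EpochSet,
    channels: tuple[str, ...] = MARKER_CHANNELS,
    n_bins: int = 16,
    lags: tuple[int, int] = (1, 32),
) -> float:
    """aMI: lagged self-information averaged over lags, channels and epochs."""
    clean = es.clean_epochs()
    if clean.shape[0] == 0:
        raise NoUnmaskedEpochsError("no unmasked epochs for aMI")
    idx = [es.channel_index(ch) for ch in channels]
    lag_range = range(lags[0], lags[1] + 1)
    vals = [
        lagged_auto_information(epoch[ci], lag_range, n_bins).mean()
        for epoch in clean
        for ci in idx
    ]
    return float(np.mean(vals))


def cross_mutual_information(
    es: EpochSet,
    pairs: tuple[tuple[str, str], ...],
    n_bins: int = 16,
) -> float:
    """cMI: zero-lag mutual information averaged over pairs and epochs.

    Symmetric in the pair order and >= 0 by construction of the plug-in
    estimator.
    """
    clean = es.clean_epochs()
    if clean.shape[0] == 0:
        raise NoUnmaskedEpochsError("no unmasked epochs for cMI")
    vals = [
        binned_mutual_information(
            epoch[es.channel_index(a)], epoch[es.channel_index(b)], n_bins
        )
        for epoch in clean
        for a, b in pairs
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# coherence


def coherence(
    es: EpochSet,
    pairs: tuple[tuple[str, str], ...],
    freq_range: tuple[float, float] = (1.0, 30.0),
    min_epochs: int = 8,
) -> float:
    """Magnitude-squared coherence averaged over 1-30 Hz and the pair set.

    MSC(f) = |<S_xy>|^2 / (<S_xx><S_yy>) with Hann-tapered cross-spectra
    averaged over unmasked epochs. A minimum number of epochs is enforced
    because single-segment MSC is identically 1.
    """
    clean = es.clean_epochs()
    if clean.shape[0] < min_epochs:
        raise InsufficientEpochsError(
            f"coherence needs >= {min_epochs} unmasked epochs, got {clean.shape[0]}"
        )
    n = clean.shape[-1]
    window = np.hanning(n)
    spectra = np.fft.rfft(clean * window, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / es.sample_rate)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    vals = []
    for a, b in pairs:
        x = spectra[:, es.channel_index(a), :]
        y = spectra[:, es.channel_index(b), :]
        sxy = (x * np.conj(y)).mean(axis=0)
        sxx = (np.abs(x) ** 2).mean(axis=0)
        syy = (np.abs(y) ** 2).mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            msc = np.abs(sxy) ** 2 / (sxx * syy)
        vals.append(float(np.nanmean(msc[sel])))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# aggregation


def aggregate_markers(
    values: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Unweighted mean over the unmasked entries of a per-epoch/channel array."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NoUnmaskedEpochsError("empty value set to aggregate")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        values = values[~mask]
        if values.size == 0:
            raise NoUnmaskedEpochsError("all values masked in aggregation")
    return float(values.mean())


def compute_marker_vector(
    es_rec: EpochSet,
    es_enc: EpochSet,
    config: MarkerConfig | None = None,
    subject_id: str = "S000",
) -> MarkerVector:
    """Compute all 12 global EEG markers for one subject.

    The IAF is measured in the eyes-closed resting phase and anchors the
    individualized band edges used for the encoding-phase band powers; all
    remaining markers are computed on the encoding phase per the marker
    channel/pair assignment.
    """
    cfg = config or MarkerConfig()
    spec_rec = estimate_spectrum(es_rec)
    iaf = compute_iaf(spec_rec)
    bands = band_edges(iaf)
    spec_enc = estimate_spectrum(es_enc)
    powers = relative_band_power(
        spec_enc, bands, denominator=cfg.power_denominator
    )
    return MarkerVector(
        iaf=iaf,
        band_powers=powers,
        ami=auto_mutual_information(
            es_enc, n_bins=cfg.n_bins, lags=cfg.ami_lags
        ),
        coherence_inter=coherence(es_enc, INTER_PAIRS, cfg.coherence_range),
        coherence_intra=coherence(es_enc, INTRA_PAIRS, cfg.coherence_range),
        cmi_inter=cross_mutual_information(es_enc, INTER_PAIRS, cfg.n_bins),
        cmi_intra=cross_mutual_information(es_enc, INTRA_PAIRS, cfg.n_bins),
        n_epochs_rec=es_rec.n_clean,
        n_epochs_enc=es_enc.n_clean,
        subject_id=subject_id,
    )
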