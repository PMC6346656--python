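"""Synthetic cohort generator with known ground truth.

Emulates the study conditions of a mild-dementia cohort (very mild to mild
Alzheimer's disease): per subject, two 30-s EEG phases (eyes-closed rest and
visual-verbal memory encoding) at 256 Hz on the 19-channel 10-20 montage with
EOG/ECG auxiliaries, a table of 13 regional MRI features plus total
intracranial volume, demographics, and MMSE/CDR outcomes generated from a
planted linear model on a known marker subset.

The EEG signal model is deliberately minimal while exposing every marker the
pipeline measures:

* a narrowband alpha oscillator at the subject's true individual alpha
  frequency (IAF), posterior-dominant, strong at rest and suppressed during
  the eyes-open encoding phase;
* Gaussian noise spectrally shaped to a configurable relative-power profile
  over the six IAF-anchored bands (delta ... beta2);
* a weak 1/f background;
* shared band-shaped sources between configured channel pairs, so that the
  magnitude-squared coherence of a pair is controlled by its coupling
  strength (coupling 1 with no independent noise means identical signals);
* stereotyped blink (300-ms biphasic, frontal) and QRS (spike train at the
  configured heart rate) artifacts, mirrored strongly into the EOG/ECG
  auxiliaries so the removal stages have references to work with.

Everything is reproducible: the cohort seed plus subject index plus phase
fully determine each stream (`numpy.random.default_rng` seeded with a fixed
tuple), so the same configuration yields bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    MissingMarkerError,
    NonPositiveDefiniteError,
)
from .markers import (
    BAND_NAMES,
    EEG_MARKER_NAMES,
    INTER_PAIRS,
    INTRA_PAIRS,
    POSTERIOR_CHANNELS,
    band_edges,
)
from .mri import MRI_FEATURE_NAMES
from .recording import CHANNELS_1020, EEGRecording, check_phase

_PHASE_CODE = {"REC": 0, "ENC": 1}

#: Regional means (volumes in cm^3, thicknesses in mm) typical of an early-AD
#: cohort, used as generator defaults.
MRI_DEFAULT_MEANS: dict[str, float] = {
    "vol_frontal": 122.91,
    "vol_parietal": 77.31,
    "vol_temporal_left": 38.45,
    "vol_temporal_right": 38.48,
    "vol_occipital": 35.97,
    "thk_frontal": 2.12,
    "thk_parietal": 1.78,
    "thk_temporal_left": 2.27,
    "thk_temporal_right": 2.34,
    "thk_occipital": 1.60,
    "vol_entorhinal": 2.82,
    "vol_hippocampus": 6.28,
    "vol_amygdala": 2.27,
}

MRI_DEFAULT_SDS: dict[str, float] = {
    "vol_frontal": 17.41,
    "vol_parietal": 11.61,
    "vol_temporal_left": 6.22,
    "vol_temporal_right": 6.13,
    "vol_occipital": 5.48,
    "thk_frontal": 0.22,
    "thk_parietal": 0.19,
    "thk_temporal_left": 0.30,
    "thk_temporal_right": 0.33,
    "thk_occipital": 0.12,
    "vol_entorhinal": 0.67,
    "vol_hippocampus": 1.19,
    "vol_amygdala": 0.55,
}

#: Six-marker subset planted by default in the outcome model (a structural
#: MRI + oscillatory EEG mix: left temporal volume, three lobar thicknesses,
#: theta and alpha2 relative power).
DEFAULT_PLANTED_BETAS: dict[str, float] = {
    "vol_temporal_left": 0.25,
    "thk_frontal": 0.35,
    "thk_parietal": 0.35,
    "thk_occipital": 0.15,
    "power_theta": -0.35,
    "power_alpha2": 0.15,
}


def _default_coupling() -> dict[tuple[str, str], float]:
    cpl: dict[tuple[str, str], float] = {}
    for pair in INTER_PAIRS:
        cpl[pair] = 0.57
    for pair in INTRA_PAIRS:
        cpl[pair] = 0.41
    return cpl


def _default_band_profile() -> dict[str, float]:
    # Mean relative-power profile of a mild-AD encoding EEG.
    return {
        "delta": 0.11,
        "theta": 0.15,
        "alpha1": 0.09,
        "alpha2": 0.07,
        "beta1": 0.15,
        "beta2": 0.17,
    }


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    The defaults reproduce the study conditions: 111 subjects, IAF
    9.71 +/- 0.44 Hz, the mild-AD band-power profile, moderate
    inter/intrahemispheric coupling, a planted six-marker outcome model with
    population R^2 = 0.382 on MMSE, and an MMSE distribution of 23.4 +/- 3.1
    clipped to [0, 30].
    """

    n_subjects: int = 111
    seed: int = 0

    # --- EEG signal model ---
    iaf_mean: float = 9.71
    iaf_sd: float = 0.44
    band_profile: dict[str, float] = field(default_factory=_default_band_profile)
    band_profile_jitter: float = 0.15  # lognormal sd of per-subject profile
    coupling: dict[tuple[str, str], float] = field(default_factory=_default_coupling)
    coupling_jitter: float = 0.05
    alpha_amp_rec: float = 20.0  # uV peak, posterior, eyes closed
    alpha_amp_enc: float = 0.0  # alpha suppressed with open eyes
    band_noise_power: float = 100.0  # uV^2 integrated over the six bands
    background_power: float = 2.0  # uV^2, 1/f-shaped, 1-45 Hz
    sensor_noise_sd: float = 1.0  # uV white noise per channel

    # --- artifacts ---
    artifact_rate: float = 10.0  # blink events per minute; 0 disables artifacts
    heart_rate_bpm: float = 70.0
    blink_amp: float = 250.0  # uV on the vertical EOG
    ecg_amp: float = 600.0  # uV QRS amplitude on the ECG auxiliary
    qrs_leak_amp: float = 4.0  # uV leaked into every scalp channel

    # --- MRI model ---
    mri_means: dict[str, float] = field(default_factory=lambda: dict(MRI_DEFAULT_MEANS))
    mri_sds: dict[str, float] = field(default_factory=lambda: dict(MRI_DEFAULT_SDS))
    mri_cov: np.ndarray | float | None = None  # None -> default block correlation
    icv_mean: float = 1500.0  # cm^3
    icv_sd: float = 130.0

    # --- outcome model ---
    effect_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_BETAS)
    )
    covariate_beta: dict[str, float] = field(
        default_factory=lambda: {"age": -0.20, "sex": -0.10, "education": 0.15}
    )
    population_r2: float | None = 0.382
    noise_sd: float | None = None  # used when population_r2 is None
    mmse_mean: float = 23.4
    mmse_sd: float = 3.1
    mmse_range: tuple[int, int] = (0, 30)
    cdr_mild_fraction: float = 38 / 111  # fraction assigned CDR 1
    cdr_noise_sd: float = 1.2  # in units of the latent-score SD

    # --- demographics ---
    age_mean: float = 74.6
    age_sd: float = 8.1
    female_fraction: float = 61 / 111
    education_mean: float = 10.9
    education_sd: float = 2.9

    duration_s: float = 30.0
    sample_rate: float = 256.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not 8.0 <= self.iaf_mean <= 13.0:
            raise ConfigError("iaf_mean must lie within [8, 13] Hz")
        for pair, c in self.coupling.items():
            if not 0.0 <= c <= 1.0:
                raise ConfigError(f"coupling_strength for {pair} must be in [0,1]")
        if set(self.band_profile) != set(BAND_NAMES):
            raise ConfigError(
                f"band_profile must define exactly the bands {BAND_NAMES}"
            )
        if any(v < 0 for v in self.band_profile.values()):
            raise ConfigError("band_profile values must be >= 0")
        lo, hi = self.mmse_range
        if (lo, hi) != (0, 30):
            raise ConfigError("mmse_range is fixed to the MMSE scale [0, 30]")


@dataclass
class SubjectTruth:
    """Ground-truth latent parameters for one subject."""

    iaf: float
    band_profile: dict[str, float]  # normalized to sum 1
    coupling: dict[tuple[str, str], float]
    ami: float
    cmi_inter: float
    cmi_intra: float


@dataclass
class GroundTruth:
    """Cohort-level ground truth filled in by the outcome generator."""

    planted_subset: tuple[str, ...]
    planted_betas: dict[str, float]
    latent: np.ndarray
    realized_r2: float
    noise_sd: float


# ---------------------------------------------------------------------------
# per-subject latent parameters


def subject_truth(config: CohortConfig, subject_index: int) -> SubjectTruth:
    """Deterministic per-subject latent parameters (same in REC and ENC)."""
    rng = np.random.default_rng([config.seed % (2**31), 11, subject_index])
    iaf = float(np.clip(rng.normal(config.iaf_mean, config.iaf_sd), 8.0, 13.0))
    jitter = rng.normal(0.0, config.band_profile_jitter, len(BAND_NAMES))
    prof = np.array([config.band_profile[b] for b in BAND_NAMES]) * np.exp(jitter)
    total = prof.sum()
    profile = {b: float(p / total) for b, p in zip(BAND_NAMES, prof)}
    coupling = {}
    for pair, c in config.coupling.items():
        coupling[pair] = float(
            np.clip(c + rng.normal(0.0, config.coupling_jitter), 0.0, 1.0)
        )
    ami = float(rng.normal(0.31, 0.01))
    cmi_inter = float(rng.normal(0.19, 0.01))
    cmi_intra = float(rng.normal(0.17, 0.01))
    return SubjectTruth(iaf, profile, coupling, ami, cmi_inter, cmi_intra)


# ---------------------------------------------------------------------------
# spectral synthesis helpers


def _shaped_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    psd: np.ndarray,
    exact_amplitude: bool = True,
) -> np.ndarray:
    """Noise with the given one-sided PSD (uV^2/Hz on the rfft grid).

    With ``exact_amplitude`` the spectral magnitudes are deterministic and
    only the phases are random, so the realized band powers equal the
    configured ones instead of fluctuating chi-square-style; the time-domain
    signal is still effectively Gaussian by the central limit theorem.
    """
    amp = np.sqrt(psd * fs * n / 4.0)
    if exact_amplitude:
        phases = rng.uniform(0.0, 2 * np.pi, len(amp))
        spec = amp * np.sqrt(2.0) * np.exp(1j * phases)
    else:
        z = rng.standard_normal(len(amp)) + 1j * rng.standard_normal(len(amp))
        spec = amp * z
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = spec[-1].real
    return np.fft.irfft(spec, n)


def _band_psd(n: int, fs: float, bands: list[tuple[float, float, float]]) -> np.ndarray:
    """One-sided PSD array that is flat within each (lo, hi, power) band."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = np.zeros_like(freqs)
    for lo, hi, power in bands:
        if power <= 0 or hi <= lo:
            continue
        sel = (freqs >= lo) & (freqs < hi)
        if sel.any():
            psd[sel] += power / (hi - lo)
    return psd


def _blink_waveform(fs: float) -> np.ndarray:
    """Stereotyped 300-ms biphasic blink, unit positive peak."""
    t = np.arange(int(round(0.3 * fs))) / fs
    w = np.exp(-(((t - 0.10) / 0.045) ** 2)) - 0.45 * np.exp(
        -(((t - 0.21) / 0.070) ** 2)
    )
    return w / np.abs(w).max()


def _qrs_waveform(fs: float) -> np.ndarray:
    """QRS-like complex spanning ~120 ms, unit R amplitude."""
    t = np.arange(int(round(0.12 * fs))) / fs - 0.06
    w = (
        -0.20 * np.exp(-((t + 0.028) / 0.010) ** 2)
        + 1.00 * np.exp(-(t / 0.008) ** 2)
        - 0.30 * np.exp(-((t - 0.030) / 0.012) ** 2)
    )
    return w / np.abs(w).max()


def _spike_train(n: int, times_s: np.ndarray, fs: float, waveform: np.ndarray) -> np.ndarray:
    out = np.zeros(n)
    half = len(waveform) // 2
    for t0 in times_s:
        start = int(round(t0 * fs)) - half
        lo = max(start, 0)
        hi = min(start + len(waveform), n)
        if hi > lo:
            out[lo:hi] += waveform[lo - start : hi - start]
    return out


def heartbeat_times(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular R-peak times covering the recording."""
    interval = 60.0 / config.heart_rate_bpm
    t = rng.uniform(0.1, 0.1 + interval)
    times = []
    while t < config.duration_s - 0.1:
        times.append(t)
        t += interval + rng.normal(0.0, 0.01)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# operations


def generate_eeg(config: CohortConfig, subject_index: int, phase: str) -> EEGRecording:
    """Synthesize one 30-s, 256-Hz, 19-channel recording plus auxiliaries.

    The alpha oscillator sits at the subject's true IAF and is strongest on
    the posterior channels in the eyes-closed REC phase; band-shaped noise
    follows the subject's band profile; configured channel pairs share a
    source so their coherence tracks the coupling strength; blinks and QRS
    artifacts are injected at the configured rates (``artifact_rate = 0``
    disables both, leaving a clean ECG auxiliary).
    """
    check_phase(phase)
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(
            f"subject_index {subject_index} outside cohort of {config.n_subjects}"
        )
    truth = subject_truth(config, subject_index)
    rng = np.random.default_rng(
        [config.seed % (2**31), 21, subject_index, _PHASE_CODE[phase]]
    )
    fs = config.sample_rate
    n = int(round(config.duration_s * fs))
    n_ch = len(CHANNELS_1020)
    t = np.arange(n) / fs

    edges = {b.name: (b.lo, b.hi) for b in band_edges(truth.iaf)}
    band_list = [
        (edges[b][0], edges[b][1], truth.band_profile[b] * config.band_noise_power)
        for b in BAND_NAMES
    ]
    psd = _band_psd(n, fs, band_list)

    # background 1/f noise over 1-45 Hz
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    bg_psd = np.zeros_like(freqs)
    sel = (freqs >= 1.0) & (freqs <= 45.0)
    shape = 1.0 / freqs[sel]
    bg_psd[sel] = config.background_power * shape / np.trapezoid(shape, freqs[sel])

    # Structured coupling: one global shared source gives every coupled
    # channel the within-hemisphere (intra) MSC level; one extra shared
    # source per homologous pair lifts the interhemispheric pairs to their
    # own target. Targets are met exactly when intra <= inter; otherwise
    # the weights are clipped into feasibility.
    coupling = truth.coupling
    intra_sqrt = [
        np.sqrt(c) for p, c in coupling.items() if p not in INTER_PAIRS and c > 0
    ]
    h2 = float(np.mean(intra_sqrt)) if intra_sqrt else 0.0
    inter_f2 = {
        p: max(0.0, float(np.sqrt(c)) - h2)
        for p, c in coupling.items()
        if p in INTER_PAIRS and c > 0
    }
    coupled = {ch for p, c in coupling.items() if c > 0 for ch in p}
    global_source = _shaped_noise(rng, n, fs, psd) if h2 > 0 else None
    pair_sources = {
        p: _shaped_noise(rng, n, fs, psd)
        for p, f2 in sorted(inter_f2.items())
        if f2 > 0
    }
    data = np.zeros((n_ch, n))
    for ci, ch in enumerate(CHANNELS_1020):
        shared: list[tuple[np.ndarray, float]] = []
        if global_source is not None and ch in coupled:
            shared.append((global_source, h2))
        for p, f2 in sorted(inter_f2.items()):
            if ch in p and f2 > 0:
                shared.append((pair_sources[p], f2))
        tot = sum(w for _, w in shared)
        w0 = max(0.0, 1.0 - tot)
        own = _shaped_noise(rng, n, fs, psd)
        sig = np.sqrt(w0) * own
        for s, w in shared:
            sig = sig + np.sqrt(w) * s
        norm = np.sqrt(w0 + tot)
        data[ci] = sig / norm if norm > 0 else sig
        if config.background_power > 0:
            data[ci] += _shaped_noise(rng, n, fs, bg_psd)

    # posterior-dominant alpha oscillator at the true IAF (common source)
    alpha_amp = config.alpha_amp_rec if phase == "REC" else config.alpha_amp_enc
    if alpha_amp > 0:
        phi = rng.uniform(0, 2 * np.pi)
        alpha = np.sin(2 * np.pi * truth.iaf * t + phi)
        for ci, ch in enumerate(CHANNELS_1020):
            w = 1.0 if ch in POSTERIOR_CHANNELS else 0.25
            data[ci] += alpha_amp * w * alpha

    if config.sensor_noise_sd > 0:
        data += rng.normal(0.0, config.sensor_noise_sd, data.shape)

    # auxiliaries
    eogv = rng.normal(0.0, 5.0, n)
    eogh = rng.normal(0.0, 5.0, n)
    beat_times = heartbeat_times(config, rng)
    qrs = _spike_train(n, beat_times, fs, _qrs_waveform(fs))
    ecg = config.ecg_amp * qrs + rng.normal(0.0, 10.0, n)

    if config.artifact_rate > 0:
        n_blinks = rng.poisson(config.artifact_rate * config.duration_s / 60.0)
        blink_t = np.sort(rng.uniform(0.3, config.duration_s - 0.4, n_blinks))
        blink = _spike_train(n, blink_t, fs, _blink_waveform(fs))
        frontal_weight = {
            "Fp1": 0.5, "Fp2": 0.5, "F7": 0.2, "F8": 0.2,
            "F3": 0.2, "F4": 0.2, "Fz": 0.12,
        }
        for ci, ch in enumerate(CHANNELS_1020):
            w = frontal_weight.get(ch, 0.0)
            if w:
                data[ci] += config.blink_amp * w * blink
        eogv += config.blink_amp * blink
        eogh += 0.3 * config.blink_amp * blink
        data += config.qrs_leak_amp * qrs  # weak cardiac leak on all channels

    rec = EEGRecording(
        channel_labels=CHANNELS_1020,
        sample_rate=fs,
        data=data,
        aux={"EOGv": eogv, "EOGh": eogh, "ECG": ecg},
        phase=phase,
        subject_id=f"S{subject_index:03d}",
    )
    rec.log(f"synthesized seed={config.seed} subject={subject_index} phase={phase}")
    return rec


def default_mri_cov(config: CohortConfig) -> np.ndarray:
    """Block-structured covariance: lobar volumes, thicknesses and limbic
    volumes correlate 0.5 within block and 0.25 across blocks."""
    names = MRI_FEATURE_NAMES
    sds = np.array([config.mri_sds[f] for f in names])
    blocks = [names[0:5], names[5:10], names[10:13]]
    corr = np.full((len(names), len(names)), 0.25)
    for block in blocks:
        idx = [names.index(f) for f in block]
        corr[np.ix_(idx, idx)] = 0.5
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sds, sds)


def generate_mri_table(config: CohortConfig) -> pd.DataFrame:
    """Draw the per-subject regional feature table plus intracranial volume.

    Rows with non-positive draws are resampled (up to a bound, after which
    the offending values are truncated to a small positive floor), so the
    output satisfies the strict-positivity invariant for any configuration.
    """
    rng = np.random.default_rng([config.seed % (2**31), 31])
    names = MRI_FEATURE_NAMES
    means = np.array([config.mri_means[f] for f in names])
    cov = config.mri_cov
    if cov is None:
        cov = default_mri_cov(config)
    elif np.isscalar(cov):
        cov = float(cov) * np.eye(len(names))
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (len(names), len(names)) or not np.allclose(cov, cov.T):
        raise NonPositiveDefiniteError("mri_cov must be symmetric 13x13")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8 * max(eigvals.max(), 1.0):
        raise NonPositiveDefiniteError(
            f"mri_cov is not positive semi-definite (min eigenvalue {eigvals.min():.3g})"
        )

    rows = rng.multivariate_normal(means, cov, size=config.n_subjects,
                                   method="svd")
    for _ in range(100):
        bad = (rows <= 0).any(axis=1)
        if not bad.any():
            break
        rows[bad] = rng.multivariate_normal(means, cov, size=int(bad.sum()),
                                            method="svd")
    rows = np.clip(rows, 1e-6, None)

    icv = rng.normal(config.icv_mean, config.icv_sd, config.n_subjects)
    icv = np.clip(icv, rows[:, :5].max(axis=1) + 1.0, None)  # icv > any volume

    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "subject_id", [f"S{i:03d}" for i in range(config.n_subjects)])
    df["icv"] = icv
    return df


def generate_demographics(config: CohortConfig) -> pd.DataFrame:
    """Age (years), sex (1 = female) and education (years) per subject."""
    rng = np.random.default_rng([config.seed % (2**31), 41])
    n = config.n_subjects
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 50, 95).round(1)
    sex = (rng.uniform(size=n) < config.female_fraction).astype(int)
    edu = np.clip(
        np.rint(rng.normal(config.education_mean, config.education_sd, n)), 4, 20
    ).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "education": edu,
        }
    )


def generate_true_eeg_markers(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth per-subject values of the 12 EEG markers.

    These are the latent quantities the signal-processing chain estimates:
    true IAF, the true relative band-power profile, the per-pair coupling
    averaged over each marker's pair set, and latent information-theoretic
    values. Useful for statistics-layer tests that should not depend on the
    EEG measurement chain.
    """
    rows = []
    for i in range(config.n_subjects):
        tr = subject_truth(config, i)
        inter = np.mean([tr.coupling.get(p, 0.0) for p in INTER_PAIRS])
        intra = np.mean([tr.coupling.get(p, 0.0) for p in INTRA_PAIRS])
        row = {"subject_id": f"S{i:03d}", "iaf": tr.iaf}
        for b in BAND_NAMES:
            row[f"power_{b}"] = tr.band_profile[b]
        row.update(
            ami=tr.ami,
            coherence_inter=float(inter),
            coherence_intra=float(intra),
            cmi_inter=tr.cmi_inter,
            cmi_intra=tr.cmi_intra,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", *EEG_MARKER_NAMES])


def generate_outcomes(
    config: CohortConfig,
    marker_table: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate MMSE/CDR outcomes from the planted linear model.

    The latent cognition score is a linear combination of z-scored planted
    markers and covariates plus Gaussian noise; when ``population_r2`` is
    set, the noise SD is chosen so the systematic part explains that fraction
    of the latent variance. The score is mapped affinely to the MMSE scale,
    rounded half-up and clipped to [0, 30]; CDR 1 is assigned to the lowest
    latent scores (with extra noise, keeping the MMSE-CDR relation weak) so
    the configured very-mild/mild split is matched.
    """
    rng = np.random.default_rng([config.seed % (2**31), 51])
    missing = [m for m in config.effect_beta if m not in marker_table.columns]
    if missing:
        raise MissingMarkerError(
            f"planted markers absent from marker table: {missing}"
        )
    if demographics is None:
        demographics = generate_demographics(config)
    n = len(marker_table)
    if len(demographics) != n:
        raise ConfigError("marker table and demographics disagree on n_subjects")

    def zscore(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    signal = np.zeros(n)
    for marker, beta in config.effect_beta.items():
        signal += beta * zscore(marker_table[marker].to_numpy())
    for cov_name, beta in config.covariate_beta.items():
        signal += beta * zscore(demographics[cov_name].to_numpy())

    sd_signal = signal.std()
    if config.population_r2 is not None:
        r2 = config.population_r2
        if not 0 < r2 < 1:
            raise ConfigError("population_r2 must lie in (0, 1)")
        noise_sd = sd_signal * np.sqrt((1 - r2) / r2) if sd_signal > 0 else 1.0
    else:
        noise_sd = config.noise_sd if config.noise_sd is not None else 1.0

    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    latent = signal + noise
    var_latent = latent.var()
    realized_r2 = float(signal.var() / var_latent) if var_latent > 0 else 0.0

    sd_latent = latent.std()
    if sd_latent > 0:
        mmse_float = config.mmse_mean + config.mmse_sd * (latent - latent.mean()) / sd_latent
    else:
        mmse_float = np.full(n, config.mmse_mean)
    lo, hi = config.mmse_range
    mmse = np.clip(np.floor(mmse_float + 0.5), lo, hi).astype(int)

    n_mild = int(round(config.cdr_mild_fraction * n))
    latent_cdr = latent + rng.normal(0.0, config.cdr_noise_sd * max(sd_latent, 1e-12), n)
    order = np.argsort(latent_cdr)
    cdr = np.full(n, 0.5)
    cdr[order[:n_mild]] = 1.0

    outcomes = demographics.copy()
    outcomes["mmse"] = mmse
    outcomes["cdr"] = cdr
    truth = GroundTruth(
        planted_subset=tuple(sorted(config.effect_beta)),
        planted_betas=dict(config.effect_beta),
        latent=latent,
        realized_r2=realized_r2,
        noise_sd=float(noise_sd),
    )
    return outcomes, truth


def generate_marker_table(config: CohortConfig) -> pd.DataFrame:
    """Ground-truth 25-marker table: ICV-normalized MRI features + EEG markers."""
    mri = generate_mri_table(config)
    normalized = mri.copy()
    for f in MRI_FEATURE_NAMES:
        normalized[f] = mri[f] / mri["icv"]
    eeg = generate_true_eeg_markers(config)
    return normalized.drop(columns="icv").merge(eeg, on="subject_id")


def write_ground_truth_json(path, config: CohortConfig, truth: GroundTruth) -> None:
    """Sidecar JSON with the planted model and per-subject latent scores."""
    import json

    payload = {
        "planted_subset": list(truth.planted_subset),
        "planted_betas": truth.planted_betas,
        "realized_r2": truth.realized_r2,
        "noise_sd": truth.noise_sd,
        "latent": truth.latent.tolist(),
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str))
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
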