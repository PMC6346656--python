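"""Spectral backend, IAF, individualized band powers, coherence, MI markers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocog.errors import (
    ConfigError,
    DegenerateSpectrumError,
    InsufficientEpochsError,
)
from neurocog.markers import (
    INTER_PAIRS,
    INTRA_PAIRS,
    MARKER_CHANNELS,
    POSTERIOR_CHANNELS,
    SpectralEstimate,
    auto_mutual_information,
    band_edges,
    coherence,
    compute_iaf,
    cross_mutual_information,
    estimate_spectrum,
    relative_band_power,
)
from neurocog.recording import CHANNELS_1020

from conftest import make_epochs

FS = 128.0
N = 256  # 2-s epochs


def _epochs_from_channel_fn(fn, n_epochs=10):
    t = np.arange(N) / FS
    epochs = np.stack(
        [np.stack([fn(e, c, t) for c in range(19)]) for e in range(n_epochs)]
    )
    return make_epochs(epochs)


def _flat_spectrum(power_fn):
    freqs = np.arange(0, FS / 2 + 0.5, 0.5)
    power = np.zeros((1, 19, len(freqs)))
    for i, f in enumerate(freqs):
        power[:, :, i] = power_fn(f)
    return SpectralEstimate(freqs, power, CHANNELS_1020, "REC")


# ---------------------------------------------------------------------------
# spectrum


def test_sinusoid_power_concentrates_and_satisfies_parseval():
    t = np.arange(N) / FS
    x = np.sin(2 * np.pi * 10.0 * t)
    es = make_epochs(np.tile(x, (1, 19, 1)).reshape(1, 19, N))
    spec = estimate_spectrum(es)
    assert spec.df == 0.5
    total = spec.power[0, 0].sum() * spec.df
    assert total == pytest.approx(x.var(), rel=0.01)
    peak = spec.frequencies[np.argmax(spec.power[0, 0])]
    assert peak == pytest.approx(10.0, abs=0.5)


def test_white_noise_spectrum_flat(rng):
    es = make_epochs(rng.normal(size=(1000, 19, N)))
    spec = estimate_spectrum(es)
    sel = (spec.frequencies >= 1) & (spec.frequencies <= 30)
    mean_psd = spec.power[:, 0, sel].mean(axis=0)
    assert mean_psd.max() / mean_psd.min() < 1.25  # Monte-Carlo tolerance


def test_constant_signal_has_no_power_above_dc():
    es = make_epochs(np.full((1, 19, N), 5.0))
    spec = estimate_spectrum(es)
    assert np.all(spec.power[0, 0, spec.frequencies >= 1.0] < 1e-20)


def test_masked_epochs_excluded_from_spectrum(rng):
    epochs = rng.normal(size=(4, 19, N))
    es = make_epochs(epochs)
    es.artifact_mask[2] = True
    spec = estimate_spectrum(es)
    assert spec.power.shape[0] == 3


# ---------------------------------------------------------------------------
# IAF


def test_iaf_point_mass_centroid():
    spec = _flat_spectrum(lambda f: 1.0 if f == 10.0 else 0.0)
    assert compute_iaf(spec) == pytest.approx(10.0, abs=1e-12)


def test_iaf_uniform_centroid_is_midpoint():
    spec = _flat_spectrum(lambda f: 1.0)
    assert compute_iaf(spec) == pytest.approx(10.5, abs=1e-12)


def test_iaf_symmetric_peaks_average():
    spec = _flat_spectrum(lambda f: 1.0 if f in (9.0, 12.0) else 0.0)
    assert compute_iaf(spec) == pytest.approx(10.5, abs=1e-12)


def test_iaf_zero_alpha_power_rejected():
    spec = _flat_spectrum(lambda f: 1.0 if f < 5 else 0.0)
    with pytest.raises(DegenerateSpectrumError):
        compute_iaf(spec)


# ---------------------------------------------------------------------------
# bands


@pytest.mark.parametrize(
    "iaf,band,lo,hi",
    [
        (10.0, "theta", 5.0, 8.0),
        (10.0, "beta2", 18.0, 26.0),
        (9.71, "alpha1", 7.71, 9.71),
        (8.0, "delta", 1.0, 3.0),
    ],
)
def test_band_edges_offset_arithmetic(iaf, band, lo, hi):
    bands = {b.name: b for b in band_edges(iaf)}
    assert bands[band].lo == pytest.approx(lo, abs=1e-12)
    assert bands[band].hi == pytest.approx(hi, abs=1e-12)


@given(iaf=st.floats(8.0, 13.0))
@settings(max_examples=50, deadline=None)
def test_bands_tile_without_gaps(iaf):
    bands = band_edges(iaf)
    assert bands[0].lo == pytest.approx(iaf - 7)
    assert bands[-1].hi == pytest.approx(iaf + 16)
    for a, b in zip(bands, bands[1:]):
        assert a.hi == pytest.approx(b.lo, abs=1e-12)


def test_band_edges_reject_out_of_range_anchor():
    with pytest.raises(ConfigError):
        band_edges(7.5)


# ---------------------------------------------------------------------------
# relative band power


def test_pure_tone_lands_in_its_band():
    es = _epochs_from_channel_fn(
        lambda e, c, t: np.sin(2 * np.pi * 6.0 * t), n_epochs=3
    )
    powers = relative_band_power(estimate_spectrum(es), band_edges(10.0))
    assert powers["theta"] > 0.97  # 6 Hz inside theta = [5, 8) for IAF 10
    assert sum(powers.values()) == pytest.approx(1.0, abs=1e-9)


def test_white_noise_band_power_proportional_to_bandwidth(rng):
    es = make_epochs(rng.normal(size=(400, 19, N)))
    powers = relative_band_power(estimate_spectrum(es), band_edges(10.0))
    # flat spectrum: fractions approach bandwidth / 23 Hz
    assert powers["delta"] == pytest.approx(2 / 23, rel=0.1)
    assert powers["beta2"] == pytest.approx(8 / 23, rel=0.05)


@given(seed=st.integers(0, 1000))
@settings(max_examples=20, deadline=None)
def test_band_powers_always_sum_to_one(seed):
    r = np.random.default_rng(seed)
    es = make_epochs(r.normal(size=(2, 19, N)) * r.uniform(0.1, 10))
    powers = relative_band_power(estimate_spectrum(es), band_edges(r.uniform(8, 13)))
    assert sum(powers.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(v >= 0 for v in powers.values())


def test_zero_power_rejected():
    es = make_epochs(np.zeros((2, 19, N)))
    with pytest.raises(DegenerateSpectrumError):
        relative_band_power(estimate_spectrum(es), band_edges(10.0))


# ---------------------------------------------------------------------------
# coherence


def test_identical_channels_fully_coherent(rng):
    epochs = rng.normal(size=(12, 19, N))
    epochs[:, CHANNELS_1020.index("F4")] = epochs[:, CHANNELS_1020.index("F3")]
    es = make_epochs(epochs)
    assert coherence(es, (("F3", "F4"),)) == pytest.approx(1.0, abs=1e-9)


def test_delayed_scaled_copy_fully_coherent(rng):
    # A linear time-invariant relation preserves coherence exactly.
    long = rng.normal(size=(12, N + 3))
    epochs = rng.normal(size=(12, 19, N))
    epochs[:, CHANNELS_1020.index("F3")] = long[:, 3:]
    epochs[:, CHANNELS_1020.index("F4")] = 0.5 * long[:, :-3]
    es = make_epochs(epochs)
    assert coherence(es, (("F3", "F4"),)) == pytest.approx(1.0, abs=0.02)


def test_independent_noise_bias_scales_as_one_over_epochs(rng):
    vals = []
    for _ in range(10):
        es = make_epochs(rng.normal(size=(29, 19, N)))
        vals.append(coherence(es, (("F3", "F4"),)))
    assert np.mean(vals) == pytest.approx(1 / 29, rel=0.30)
    for _ in range(3):
        es = make_epochs(rng.normal(size=(120, 19, N)))
        assert coherence(es, (("F3", "F4"),)) < 2 / 100


def test_too_few_epochs_rejected(rng):
    es = make_epochs(rng.normal(size=(5, 19, N)))
    with pytest.raises(InsufficientEpochsError):
        coherence(es, INTER_PAIRS)


# ---------------------------------------------------------------------------
# MI markers


def test_cmi_independent_channels_near_zero(rng):
    es = make_epochs(rng.normal(size=(20, 19, N)))
    # permutation-null bound for the 16-bin estimator at 256 samples
    assert cross_mutual_information(es, (("F3", "F4"),)) < 0.65
    assert cross_mutual_information(es, (("F3", "F4"),)) >= 0.0


def test_cmi_identical_channels_reach_log_bins(rng):
    epochs = rng.normal(size=(5, 19, N))
    epochs[:, CHANNELS_1020.index("O2")] = epochs[:, CHANNELS_1020.index("O1")]
    es = make_epochs(epochs)
    assert cross_mutual_information(es, (("O1", "O2"),)) == pytest.approx(
        np.log(16), rel=1e-9
    )


def test_cmi_symmetric_in_pair_order(rng):
    es = make_epochs(rng.normal(size=(6, 19, N)))
    assert cross_mutual_information(es, (("F3", "C3"),)) == pytest.approx(
        cross_mutual_information(es, (("C3", "F3"),)), abs=1e-12
    )


def test_ami_positive_and_higher_for_structured_signals(rng):
    t = np.arange(N) / FS
    osc = _epochs_from_channel_fn(lambda e, c, t_: np.sin(2 * np.pi * 8 * t_), 4)
    noise = make_epochs(rng.normal(size=(4, 19, N)))
    ami_osc = auto_mutual_information(osc)
    ami_noise = auto_mutual_information(noise)
    assert ami_osc > ami_noise > 0


def test_marker_channel_sets_follow_topography():
    # Posterior set for the resting rhythm; fronto-central-occipital set and
    # homologous/within-hemisphere pairs for the task markers.
    assert POSTERIOR_CHANNELS == ("P3", "Pz", "P4", "O1", "O2")
    assert set(MARKER_CHANNELS) == {"F3", "F4", "C3", "C4", "O1", "O2"}
    assert INTER_PAIRS == (("F3", "F4"), ("C3", "C4"), ("O1", "O2"))
    assert set(INTRA_PAIRS) == {
        ("F3", "C3"), ("F3", "O1"), ("C3", "O1"),
        ("F4", "C4"), ("F4", "O2"), ("C4", "O2"),
    }
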