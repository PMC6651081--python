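import numpy as np
import pytest
from hypothesis import given, strategies as st

import ewtwt as ew
from ewtwt.ewt import meyer_taper

FS = 360.0


def tone(freq_hz, n, fs=FS, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.cos(2 * np.pi * freq_hz * t)


def random_boundaries(rng, max_count=4):
    k = rng.integers(1, max_count + 1)
    b = np.sort(rng.uniform(0.05, np.pi - 0.05, size=k))
    # enforce separation so auto-gamma stays well-conditioned
    while np.any(np.diff(np.concatenate([[0], b, [np.pi]])) < 0.05):
        b = np.sort(rng.uniform(0.05, np.pi - 0.05, size=k))
    return ew.BoundarySet(b)


# ---------------------------------------------------------------- spectrum

def test_constant_signal_energy_all_in_dc():
    spec = ew.compute_spectrum(ew.Signal(np.ones(500), FS))
    assert spec.magnitudes[0] == pytest.approx(500.0)
    assert np.all(spec.magnitudes[1:] < 1e-10)
    assert spec.freqs_rad[0] == 0.0
    assert spec.magnitudes.size == 500 // 2 + 1


def test_pure_cosine_at_quarter_rate_peaks_at_half_pi():
    n = 1024
    spec = ew.compute_spectrum(ew.Signal(tone(FS / 4, n), FS))
    k = int(np.argmax(spec.magnitudes))
    assert spec.freqs_rad[k] == pytest.approx(np.pi / 2)
    assert spec.freqs_hz[k] == pytest.approx(FS / 4)


def test_two_tone_spectrum_matches_direct_dft_oracle():
    """Window-periodic 0.5 + 10 Hz tones: two dominant bins, values equal to
    an independent direct DFT summation."""
    n = 3600  # 10 s at 360 Hz -> 0.5 Hz = bin 5, 10 Hz = bin 100
    x = tone(0.5, n) + tone(10.0, n)
    spec = ew.compute_spectrum(ew.Signal(x, FS))

    # independent oracle: direct DFT sum at every half-spectrum bin
    k = np.arange(n // 2 + 1)
    oracle = np.abs(np.exp(-2j * np.pi * np.outer(k[:150], np.arange(n)) / n) @ x)
    np.testing.assert_allclose(spec.magnitudes[:150], oracle, atol=1e-8)

    dominant = np.flatnonzero(spec.magnitudes > 0.01 * spec.magnitudes.max())
    assert set(dominant) == {5, 100}


def test_spectrum_rejects_non_finite():
    with pytest.raises(ValueError):
        ew.compute_spectrum(ew.Signal([0.0, np.inf, 1.0], FS))


# ---------------------------------------------------------------- boundaries

def _bump_spectrum(centers_rad, heights, n_bins=1000, width_bins=25, fs=2 * np.pi):
    """Spectrum with triangular bumps wide enough to survive smoothing."""
    freqs = np.linspace(0.0, np.pi, n_bins)
    mags = np.zeros(n_bins)
    for c, h in zip(centers_rad, heights):
        idx = int(round(c / np.pi * (n_bins - 1)))
        lo, hi = max(0, idx - width_bins), min(n_bins, idx + width_bins + 1)
        mags[lo:hi] += h * (1.0 - np.abs(np.arange(lo, hi) - idx) / (width_bins + 1))
    return ew.Spectrum(mags, freqs, freqs * fs / (2 * np.pi)), freqs


def test_two_maxima_midpoint():
    spec, freqs = _bump_spectrum([0.5, 1.5], [2.0, 1.0])
    bs = ew.detect_boundaries(spec, n_segments=2)
    i, j = int(round(0.5 / np.pi * 999)), int(round(1.5 / np.pi * 999))
    assert bs.boundaries_rad[0] == (freqs[i] + freqs[j]) / 2
    assert bs.boundaries_rad[0] == pytest.approx(1.0, abs=0.005)
    assert bs.method == "maxima"


def test_three_maxima_hand_oracle():
    centers = [0.4, 0.8, 2.0]
    spec, freqs = _bump_spectrum(centers, [3.0, 2.0, 1.0])
    bs = ew.detect_boundaries(spec, n_segments=3, min_freq_hz=0.0)
    idx = [int(round(c / np.pi * 999)) for c in centers]
    expected = [(freqs[idx[0]] + freqs[idx[1]]) / 2, (freqs[idx[1]] + freqs[idx[2]]) / 2]
    np.testing.assert_array_equal(bs.boundaries_rad, expected)
    np.testing.assert_allclose(bs.boundaries_rad, [0.6, 1.4], atol=0.005)


def test_boundary_between_artifact_and_ecg_band(default_spec):
    """Artifact peak near 0.3 Hz vs ECG fundamental near 1.8 Hz: the detected
    boundary falls between them, near 1 Hz."""
    fs = default_spec.fs
    to_rad = 2 * np.pi / fs
    spec, _ = _bump_spectrum([0.3 * to_rad, 1.8 * to_rad], [5.0, 2.0],
                             n_bins=4000, width_bins=30, fs=fs)
    bs = ew.detect_boundaries(spec, n_segments=2, smooth_window=1)
    hz = bs.boundaries_hz[0]
    assert 0.5 < hz < 1.5


def test_min_freq_pruning_drops_low_boundary():
    spec, _ = _bump_spectrum([0.05, 0.5, 2.0], [5.0, 3.0, 1.0], fs=2 * np.pi)
    bs = ew.detect_boundaries(spec, n_segments=3, min_freq_hz=0.3)
    # first midpoint ~0.275 rad = 0.275 Hz at fs=2pi -> pruned
    assert bs.boundaries_rad.size == 1
    assert bs.boundaries_rad[0] == pytest.approx(1.25, abs=0.01)


def test_equal_energy_fallback_is_flagged():
    freqs = np.linspace(0.0, np.pi, 512)
    mags = np.exp(-3 * freqs)  # monotone: no interior maxima
    spec = ew.Spectrum(mags, freqs, freqs)
    bs = ew.detect_boundaries(spec, n_segments=3)
    assert bs.method == "equal_energy"
    assert bs.boundaries_rad.size >= 1


def test_all_zero_spectrum_errors():
    freqs = np.linspace(0.0, np.pi, 64)
    with pytest.raises(ValueError):
        ew.detect_boundaries(ew.Spectrum(np.zeros(64), freqs, freqs), 2)


# ---------------------------------------------------------------- filter bank

def test_meyer_taper_closed_forms():
    assert meyer_taper(0.0) == 0.0
    assert meyer_taper(1.0) == pytest.approx(1.0)  # 35 - 84 + 70 - 20 = 1
    assert meyer_taper(0.5) == pytest.approx(0.5)
    x = np.linspace(0, 1, 101)
    np.testing.assert_allclose(meyer_taper(x) + meyer_taper(1 - x), 1.0, atol=1e-12)


def test_single_boundary_filter_matches_pointwise_construction():
    """Scaling filter around pi/2 with gamma=0.2: flat to 0.8*pi/2, zero from
    1.2*pi/2, cosine-taper transition computed independently."""
    w, g, n = np.pi / 2, 0.2, 1024
    bank = ew.build_filter_bank(ew.BoundarySet([w]), n, gamma=g)
    k = np.arange(n)
    omega = np.minimum(2 * np.pi * k / n, 2 * np.pi - 2 * np.pi * k / n)
    tau = g * w
    expected = np.where(
        omega <= w - tau, 1.0,
        np.where(omega >= w + tau, 0.0,
                 np.cos(np.pi / 2 * meyer_taper((omega - w + tau) / (2 * tau)))),
    )
    np.testing.assert_allclose(bank.scaling, expected, atol=1e-12)


def test_partition_of_unity_random_banks():
    rng = np.random.default_rng(7)
    for _ in range(20):
        bs = random_boundaries(rng)
        n = int(rng.choice([256, 511, 1024, 2000]))
        bank = ew.build_filter_bank(bs, n)
        assert bank.partition_of_unity_error() < 1e-10
        for f in bank.filters:
            assert np.all(f >= -1e-12) and np.all(f <= 1 + 1e-12)
            np.testing.assert_allclose(f[1:], f[1:][::-1], atol=1e-12)  # symmetric


def test_overlapping_gamma_rejected():
    bs = ew.BoundarySet([0.5, 0.6])
    with pytest.raises(ValueError, match="overlap"):
        ew.build_filter_bank(bs, 512, gamma=0.5)


# ---------------------------------------------------------------- transform

def test_sub_boundary_tone_lands_in_approximation_mode():
    n = 3600
    sig = ew.Signal(tone(0.3, n), FS)
    bank = ew.build_filter_bank(
        ew.BoundarySet([2 * np.pi * 1.0 / FS], fs=FS), n, gamma=0.5
    )
    modes = ew.ewt_forward(sig, bank)
    total = np.sum(sig.samples**2)
    assert np.sum(modes.modes[0].samples ** 2) / total > 0.999
    assert np.linalg.norm(modes.modes[1].samples) < 1e-3 * np.linalg.norm(sig.samples)


def test_two_tones_separate_with_low_crosstalk():
    n = 3600
    lo, hi = tone(0.3, n), tone(10.0, n)
    sig = ew.Signal(lo + hi, FS)
    bank = ew.build_filter_bank(
        ew.BoundarySet([2 * np.pi * 1.0 / FS], fs=FS), n, gamma=0.5
    )
    modes = ew.ewt_forward(sig, bank)
    assert np.linalg.norm(modes.modes[0].samples - lo) / np.linalg.norm(lo) < 1e-3
    assert np.linalg.norm(modes.modes[1].samples - hi) / np.linalg.norm(hi) < 1e-3


@given(st.integers(100, 2000), st.integers(0, 2**31 - 1))
def test_perfect_reconstruction_random_signals(n, seed):
    rng = np.random.default_rng(seed)
    sig = ew.Signal(rng.standard_normal(n), FS)
    bank = ew.build_filter_bank(random_boundaries(rng), n)
    modes = ew.ewt_forward(sig, bank)
    rel = np.linalg.norm
    assert rel(ew.ewt_inverse(modes).samples - sig.samples) / rel(sig.samples) < 1e-8
    total = sum(m.samples for m in modes.modes)
    assert rel(total - sig.samples) / rel(sig.samples) < 1e-8


def test_round_trip_on_synthetic_ecg(battery):
    clean, _, _ = battery
    bank = ew.build_filter_bank(
        ew.BoundarySet([2 * np.pi * 1.0 / clean.fs], fs=clean.fs), len(clean)
    )
    rec = ew.ewt_inverse(ew.ewt_forward(clean, bank))
    assert np.max(np.abs(rec.samples - clean.samples)) < 1e-8 * np.max(np.abs(clean.samples))


def test_zeroed_approximation_of_sub_boundary_tone_kills_output():
    n = 3600
    sig = ew.Signal(tone(0.3, n), FS)
    bank = ew.build_filter_bank(
        ew.BoundarySet([2 * np.pi * 1.0 / FS], fs=FS), n, gamma=0.5
    )
    modes = ew.ewt_forward(sig, bank)
    modes.coeffs[0] = np.zeros(n)
    out = ew.ewt_inverse(modes)
    assert np.linalg.norm(out.samples) < 1e-3 * np.linalg.norm(sig.samples)


def test_length_mismatch_errors():
    bank = ew.build_filter_bank(ew.BoundarySet([1.0]), 512)
    with pytest.raises(ValueError, match="length"):
        ew.ewt_forward(ew.Signal(np.zeros(500), FS), bank)


# ---------------------------------------------------------------- estimator

def test_estimator_sklearn_contract(battery):
    from sklearn.base import clone

    _, noisy, _ = battery
    est = ew.EmpiricalWaveletTransform(fs=noisy.fs, boundaries_hz=[1.0])
    est2 = clone(est)
    assert est2.get_params() == est.get_params()
    modes = est.fit(noisy).transform(noisy)
    assert modes.shape == (2, len(noisy))
    np.testing.assert_allclose(modes.sum(axis=0), noisy.samples, atol=1e-8)
    back = est.inverse_transform([c for c in est.decompose(noisy).coeffs])
    np.testing.assert_allclose(back, noisy.samples, atol=1e-8)
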