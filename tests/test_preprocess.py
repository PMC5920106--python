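import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.signal import butter, sosfreqz

from alphap1 import fibonacci_montage
from alphap1.errors import ConfigError, NoUsableTrialsError, PipelineOrderError
from alphap1.preprocess import (
    apply_laplacian,
    bandpass_filter,
    baseline_subtract,
    interpolate_channels,
    reject_epochs,
    spherical_spline_operators,
)

from conftest import make_epochs


# --- rejection ------------------------------------------------------------


def test_rejection_threshold_is_strict_and_logged(rng):
    data = rng.uniform(-10, 10, size=(4, 5, 50))
    data[1, 2, 7] = 80.0        # clearly beyond +/-75 -> rejected
    data[2] = 0.0               # all zeros -> kept
    data[3, 0, 0] = 75.0        # exact boundary -> kept (strict inequality)
    data[3, 1, 1] = -75.0
    epochs = make_epochs(data)
    kept, log = reject_epochs(epochs, 75.0)
    assert list(log["kept"]) == [True, False, True, True]
    assert kept.n_trials == 3
    assert log.loc[1, "max_abs_uV"] == pytest.approx(80.0)
    # pure filter: surviving values bitwise unchanged, order preserved
    np.testing.assert_array_equal(kept.data, data[[0, 2, 3]])


def test_rejecting_every_epoch_names_the_subject(rng):
    epochs = make_epochs(np.full((3, 5, 20), 100.0))
    with pytest.raises(NoUsableTrialsError, match="subject 0"):
        reject_epochs(epochs, 75.0)


def test_rejection_requires_voltage_domain(rng):
    epochs = make_epochs(rng.standard_normal((2, 5, 20)), units="uV/cm2")
    with pytest.raises(PipelineOrderError):
        reject_epochs(epochs, 75.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(hst.floats(min_value=1.0, max_value=200.0))
def test_rejection_partitions_epochs_by_peak_amplitude(threshold):
    rng = np.random.default_rng(0)
    data = rng.uniform(-150, 150, size=(12, 3, 30))
    epochs = make_epochs(data, montage=fibonacci_montage(3))
    peaks = np.abs(data).max(axis=(1, 2))
    if (peaks > threshold).all():
        with pytest.raises(NoUsableTrialsError):
            reject_epochs(epochs, threshold)
    else:
        kept, log = reject_epochs(epochs, threshold)
        np.testing.assert_array_equal(log["kept"].to_numpy(), peaks <= threshold)
        np.testing.assert_array_equal(kept.data, data[peaks <= threshold])


# --- filtering ------------------------------------------------------------


def _two_pass_gain(freq, low=0.05, high=25.0, order=1, fs=500.0):
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    w, h = sosfreqz(sos, worN=[freq], fs=fs)
    return np.abs(h[0]) ** 2  # forward-backward application squares |H|


@pytest.mark.parametrize("freq, rtol", [(10.0, 0.01), (100.0, 0.05)])
def test_zero_phase_butterworth_matches_squared_magnitude_response(freq, rtol):
    fs = 500.0
    t = np.arange(int(4 * fs)) / fs
    tone = np.sin(2 * np.pi * freq * t)
    epochs = make_epochs(np.tile(tone, (1, 5, 1)), sfreq=fs)
    out = bandpass_filter(epochs, 0.05, 25.0, order=1)
    # demodulate at the tone frequency over the interior: robust to the slow
    # edge transient of the 0.05 Hz high-pass pole
    interior = slice(500, -500)
    phasor = np.exp(-2j * np.pi * freq * t[interior])
    amp = 2 * np.abs(np.mean(out.data[0, 0, interior] * phasor))
    expected = _two_pass_gain(freq)
    assert amp == pytest.approx(expected, rel=rtol)
    # unity gain at the geometric passband centre of the 0.05-25 Hz design
    assert 0.99 < _two_pass_gain(np.sqrt(0.05 * 25.0)) <= 1.0


def test_filter_of_zero_signal_is_zero_and_band_is_validated():
    epochs = make_epochs(np.zeros((2, 5, 100)))
    np.testing.assert_array_equal(bandpass_filter(epochs).data, 0.0)
    with pytest.raises(ConfigError, match="Nyquist"):
        bandpass_filter(epochs, 0.05, 400.0)


def test_zero_phase_filtering_does_not_shift_the_p1_peak():
    fs = 500.0
    t = np.arange(600) / fs * 1000 - 200
    template = np.exp(-0.5 * ((t - 115) / 15.0) ** 2)
    epochs = make_epochs(np.tile(template, (1, 5, 1)), t0=-200.0)
    out = bandpass_filter(epochs, 0.05, 25.0, order=1)
    lags = np.arange(-50, 51)
    xc = [np.dot(np.roll(out.data[0, 0], lag), template) for lag in lags]
    assert lags[int(np.argmax(xc))] == 0


# --- spherical splines ----------------------------------------------------


def test_laplacian_annihilates_constant_fields():
    mont = fibonacci_montage(64)
    _, lap = spherical_spline_operators(mont)
    out = lap @ np.full(64, 3.7)
    assert np.max(np.abs(out)) < 1e-6 * 3.7


@pytest.mark.parametrize("degree, harm", [
    (1, lambda x, y, z: z),
    (2, lambda x, y, z: x * y),
    (3, lambda x, y, z: z * (x**2 - y**2)),
])
def test_laplacian_eigenproperty_on_spherical_harmonics(degree, harm):
    """A degree-l harmonic maps to ~ l(l+1) times itself (CSD orientation)."""
    mont = fibonacci_montage(128)
    _, lap = spherical_spline_operators(mont)
    x, y, z = mont.positions.T
    v = harm(x, y, z)
    v = v / np.linalg.norm(v)
    out = lap @ v
    r = np.corrcoef(out, degree * (degree + 1) * v)[0, 1]
    assert r > 0.99
    # the scale tracks l(l+1) within the spline approximation
    gain = out @ v
    assert gain == pytest.approx(degree * (degree + 1), rel=0.2)


def test_operators_are_linear(rng):
    mont = fibonacci_montage(48)
    interp, lap = spherical_spline_operators(mont)
    a, b = rng.standard_normal((2, 48))
    for op in (interp, lap):
        np.testing.assert_allclose(op @ (2.0 * a - 3.0 * b),
                                   2.0 * (op @ a) - 3.0 * (op @ b),
                                   rtol=1e-10, atol=1e-10)


def test_interpolation_reconstructs_held_out_channel_of_smooth_field():
    mont = fibonacci_montage(96)
    x, y, z = mont.positions.T
    field = 1.5 * z + 0.8 * x * y + 0.3 * (x**2 - y**2)
    data = np.repeat(field[None, :, None], 4, axis=2) * np.ones((2, 1, 1))
    epochs = make_epochs(data, montage=mont, sfreq=500.0)
    bad = [mont.names[10]]
    out = interpolate_channels(epochs, bad)
    err = np.abs(out.data[:, 10, :] - field[10]).max()
    assert err < 0.02 * np.abs(field).max()
    good = np.delete(np.arange(96), 10)
    np.testing.assert_array_equal(out.data[:, good, :], epochs.data[:, good, :])


def test_interpolation_identity_and_idempotence(rng):
    mont = fibonacci_montage(48)
    epochs = make_epochs(rng.standard_normal((3, 48, 10)), montage=mont)
    assert interpolate_channels(epochs, []) is epochs
    once = interpolate_channels(epochs, [mont.names[5]])
    twice = interpolate_channels(once, [mont.names[5]])
    np.testing.assert_allclose(twice.data, once.data, rtol=1e-9, atol=1e-12)


def test_interpolating_away_all_channels_fails():
    mont = fibonacci_montage(6)
    epochs = make_epochs(np.zeros((1, 6, 5)), montage=mont)
    with pytest.raises(ConfigError):
        interpolate_channels(epochs, list(mont.names))


def test_laplacian_flips_unit_tag_once_and_enforces_order(rng):
    epochs = make_epochs(rng.standard_normal((2, 5, 20)))
    csd = apply_laplacian(epochs)
    assert csd.units == "uV/cm2"
    assert csd.n_trials == epochs.n_trials
    with pytest.raises(PipelineOrderError):
        apply_laplacian(csd)


# --- baselining -----------------------------------------------------------


def test_baseline_subtraction_zeroes_constants_and_is_shift_invariant(rng):
    data = rng.standard_normal((3, 5, 100))
    epochs = make_epochs(data, t0=-100.0, target_ms=50.0)
    const = make_epochs(np.full((2, 5, 100), 5.0), t0=-100.0, target_ms=50.0)
    out_const = baseline_subtract(const, (-60.0, 0.0), "target")
    np.testing.assert_allclose(out_const.data, 0.0, atol=1e-12)
    out1 = baseline_subtract(epochs, (-60.0, 0.0), "target")
    shifted = baseline_subtract(epochs.with_data(data + 17.3), (-60.0, 0.0),
                                "target")
    np.testing.assert_allclose(shifted.data, out1.data, atol=1e-10)


def test_baseline_matches_brute_force_window_mean(rng):
    data = rng.standard_normal((2, 5, 80))
    epochs = make_epochs(data, t0=-80.0, target_ms=0.0)
    out = baseline_subtract(epochs, (-50.0, -10.0), "cue")
    t = epochs.times_ms
    cols = [i for i in range(80) if -50.0 <= t[i] <= -10.0]
    for tr in range(2):
        for ch in range(5):
            mean = sum(data[tr, ch, i] for i in cols) / len(cols)
            np.testing.assert_allclose(out.data[tr, ch], data[tr, ch] - mean,
                                       atol=1e-10)
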