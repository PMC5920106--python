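"""Morlet-wavelet time-frequency decomposition and alpha-band time courses.

The wavelet family spans 3-50 Hz in 1.6 Hz steps (30 centre frequencies,
3.0 ... 49.4 Hz) with the cycle count increasing linearly from 3 at the
lowest to 10 at the highest frequency. Each kernel is a complex Morlet

    w(t) = exp(2*pi*i*f*t) * exp(-t^2 / (2*sigma_t^2)),   sigma_t = c/(2*pi*f),

truncated where its Gaussian envelope falls below 1e-4 of maximum, stored at
odd length and normalized to unit energy. Unit-energy normalization is a
fixed convention: any per-kernel scale cancels in percent change, and raw
power users get energy-preserving responses.

Power is the squared magnitude of the (linear, FFT-based) convolution, and
is baselined as percent signal change against the mean raw power over a
pre-cue window pooled over all trials of all conditions (a "common
condition" baseline: the same divisor for both conditions, so the
between-condition ordering of raw power is preserved at every time point).

Samples closer to an epoch edge than half a kernel length are flagged in
``TFRPower.edge_mask`` and excluded by windowed reductions that promise
edge-clean output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft
from scipy.fft import next_fast_len

from .epochs import EpochSet
from .errors import ConfigError, DataError

ENVELOPE_CUTOFF = 1e-4
ALPHA_BAND = (8.0, 14.0)


@dataclass(frozen=True)
class WaveletFamily:
    freqs: np.ndarray  # centre frequencies, Hz
    cycles: np.ndarray
    sfreq: float
    kernels: tuple[np.ndarray, ...]  # complex, odd length, unit energy

    @property
    def half_lengths(self) -> np.ndarray:
        return np.array([(len(k) - 1) // 2 for k in self.kernels])


def build_family(fmin: float = 3.0, fmax: float = 50.0, step: float = 1.6,
                 cycles: tuple[float, float] = (3.0, 10.0),
                 sfreq: float = 500.0) -> WaveletFamily:
    """Construct the Morlet family for a frequency/cycle schedule."""
    if sfreq <= 2 * fmax:
        raise ConfigError(f"sampling rate {sfreq} Hz must exceed twice the "
                          f"maximum frequency {fmax} Hz")
    if not 0 < fmin < fmax or step <= 0:
        raise ConfigError("need 0 < fmin < fmax and step > 0")
    n_freq = int(np.floor((fmax - fmin) / step + 1e-9)) + 1
    freqs = fmin + step * np.arange(n_freq)
    if n_freq > 1:
        cyc = cycles[0] + (cycles[1] - cycles[0]) * np.arange(n_freq) / (n_freq - 1)
    else:
        cyc = np.array([cycles[0]])
    half_extent = np.sqrt(-2.0 * np.log(ENVELOPE_CUTOFF))  # in units of sigma_t
    kernels = []
    for f, c in zip(freqs, cyc):
        sigma_t = c / (2 * np.pi * f)
        half_n = int(np.ceil(half_extent * sigma_t * sfreq))
        t = np.arange(-half_n, half_n + 1) / sfreq
        k = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2 * sigma_t**2))
        k /= np.sqrt(np.sum(np.abs(k) ** 2))
        kernels.append(k)
    return WaveletFamily(freqs=freqs, cycles=cyc, sfreq=sfreq,
                         kernels=tuple(kernels))


@dataclass
class TFRPower:
    power: np.ndarray  # (trials, channels, freqs, times)
    times_ms: np.ndarray  # relative to cue onset
    target_time_ms: float
    freqs: np.ndarray
    channels: tuple[str, ...]
    kind: str = "raw"  # "raw" | "percent"
    baseline: tuple[float, float] | None = None
    edge_mask: np.ndarray | None = None  # (freqs, times) True = contaminated

    def times_rel_target(self) -> np.ndarray:
        return self.times_ms - self.target_time_ms


def decompose(epochs: EpochSet, family: WaveletFamily,
              channels=None, dtype=np.float64) -> TFRPower:
    """Raw wavelet power per trial, channel and frequency.

    ``channels`` restricts the decomposition (a group name or channel list);
    None decomposes every channel. FFT-based linear convolution in 'same'
    alignment; equivalence with direct time-domain convolution is a tested
    property, not an assumption. ``dtype`` selects the working precision:
    float64 by default; float32 halves time and memory for large simulation
    studies where power enters only window means and rank statistics.
    """
    if abs(family.sfreq - epochs.sfreq) > 1e-9:
        raise ConfigError("wavelet family sampling rate != epochs sampling rate")
    if channels is None:
        idx = np.arange(epochs.montage.n_channels)
    else:
        idx = epochs.montage.index(channels)
    dtype = np.dtype(dtype)
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    data = np.ascontiguousarray(epochs.data[:, idx, :], dtype=dtype)
    n_samp = data.shape[-1]
    n_freq = len(family.freqs)
    power = np.empty(data.shape[:2] + (n_freq, n_samp), dtype=dtype)
    edge = np.zeros((n_freq, n_samp), dtype=bool)
    # linear convolution by frequency-domain multiplication: one forward FFT
    # of the data shared by every kernel
    max_len = max(len(k) for k in family.kernels)
    nfft = next_fast_len(n_samp + max_len - 1)
    data_f = sfft.fft(data, n=nfft, axis=-1).astype(cdtype, copy=False)
    for fi, kernel in enumerate(family.kernels):
        half = (len(kernel) - 1) // 2
        if len(kernel) > n_samp:
            warnings.warn(f"wavelet at {family.freqs[fi]:.1f} Hz longer than the "
                          "epoch; whole frequency row edge-flagged", stacklevel=2)
            edge[fi, :] = True
        else:
            edge[fi, :half] = True
            if half > 0:
                edge[fi, -half:] = True
        kern_f = sfft.fft(kernel, n=nfft).astype(cdtype, copy=False)
        conv = sfft.ifft(data_f * kern_f, axis=-1)[..., half:half + n_samp]
        power[:, :, fi, :] = conv.real**2 + conv.imag**2
    return TFRPower(power=power, times_ms=epochs.times_ms,
                    target_time_ms=epochs.target_time_ms, freqs=family.freqs,
                    channels=tuple(epochs.montage.names[i] for i in idx),
                    kind="raw", edge_mask=edge)


def percent_change(tfr: TFRPower, baseline: tuple[float, float] = (-400.0, -100.0),
                   condition_labels=None) -> TFRPower:
    """Percent signal change against a pre-cue baseline.

    The baseline is the mean raw power over the window pooled across ALL
    trials (common across conditions). Passing ``condition_labels`` switches
    to per-condition baselining for sensitivity analyses.
    """
    if tfr.kind != "raw":
        raise DataError("percent_change expects raw power")
    lo, hi = baseline
    if not lo < hi <= 0:
        raise ConfigError("baseline window must be ordered and end before cue onset")
    mask = (tfr.times_ms >= lo - 1e-9) & (tfr.times_ms <= hi + 1e-9)
    if not mask.any():
        raise ConfigError(f"baseline window {baseline} contains no samples")
    def _check(B):
        if np.any(B == 0):
            ch, fr = np.argwhere(B == 0)[0]
            raise DataError(f"zero baseline power at channel {tfr.channels[ch]}, "
                            f"{tfr.freqs[fr]:.1f} Hz")
        return B

    if condition_labels is None:
        B = _check(tfr.power[:, :, :, mask].mean(axis=(0, 3)))  # (ch, freq)
        out = tfr.power * (100.0 / B)[None, :, :, None]  # 100*(P-B)/B, two passes
        out -= 100.0
    else:
        condition_labels = np.asarray(condition_labels)
        out = np.empty_like(tfr.power)
        for c in np.unique(condition_labels):
            sel = condition_labels == c
            B = _check(tfr.power[sel][:, :, :, mask].mean(axis=(0, 3)))
            out[sel] = tfr.power[sel] * (100.0 / B)[None, :, :, None] - 100.0
    return replace(tfr, power=out, kind="percent", baseline=baseline)


def band_frequencies(freqs: np.ndarray, band: tuple[float, float] = ALPHA_BAND
                     ) -> np.ndarray:
    """Indices of centre frequencies inside the closed interval ``band``."""
    lo, hi = band
    idx = np.nonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))[0]
    if len(idx) == 0:
        raise ConfigError(f"no wavelet centre frequency inside band {band}")
    return idx


def band_timecourse(tfr: TFRPower, group, band: tuple[float, float] = ALPHA_BAND
                    ) -> np.ndarray:
    """Per-trial time course: mean over band frequencies and group channels."""
    fidx = band_frequencies(tfr.freqs, band)
    if isinstance(group, str) or (len(group) and isinstance(group[0], str)):
        # resolve names against the decomposed channel subset
        lookup = {nm: i for i, nm in enumerate(tfr.channels)}
        names = [group] if isinstance(group, str) else group
        try:
            cidx = np.array([lookup[nm] for nm in names])
        except KeyError as exc:
            raise ConfigError(f"channel {exc.args[0]!r} not in decomposition") from None
    else:
        cidx = np.asarray(group, dtype=int)
    return tfr.power[:, cidx][:, :, fidx, :].mean(axis=(1, 2))


def window_mean(timecourse: np.ndarray, times_rel_event: np.ndarray,
                window: tuple[float, float],
                clean_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean of a (trials x times) course over a time window, last axis.

    ``clean_mask`` (True = usable sample) lets callers enforce wavelet
    edge-cleanliness; an edge-contaminated window raises rather than
    silently averaging padding."""
    lo, hi = window
    mask = (times_rel_event >= lo - 1e-9) & (times_rel_event <= hi + 1e-9)
    if not mask.any():
        raise ConfigError(f"window {window} contains no samples")
    if clean_mask is not None and not clean_mask[mask].all():
        raise DataError(f"window {window} overlaps wavelet edge-contaminated samples")
    return timecourse[..., mask].mean(axis=-1)


def band_clean_mask(tfr: TFRPower, band: tuple[float, float] = ALPHA_BAND
                    ) -> np.ndarray:
    """Samples clean of edge effects for every frequency in ``band``."""
    if tfr.edge_mask is None:
        return np.ones_like(tfr.times_ms, dtype=bool)
    fidx = band_frequencies(tfr.freqs, band)
    return ~tfr.edge_mask[fidx].any(axis=0)
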