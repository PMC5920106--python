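"""Synthetic epoched-EEG cohorts with known injected effects.

Each trial is the sum of

* 1/f^beta background noise, generated per channel by spectrum-shaping white
  Gaussian noise, scaled to a target RMS, then mixed across channels with a
  volume-conduction-like angular Gaussian so nearby electrodes are
  correlated (real scalp noise is spatially smooth; spatially white noise
  would be amplified unrealistically by the surface Laplacian);
* an ongoing alpha oscillation (random phase per trial, coherent across
  channels) projected through a spatial gain profile that by default is a
  broad angular-Gaussian bump centred on the left posterior channel group
  (posterior alpha is spatially smooth in real EEG). On meaning-trained trials
  its amplitude is multiplied by (1 + subject effect) inside a pre-target
  window, with 50 ms cosine ramps at the window edges to avoid spectral
  splatter;
* a target-locked Gaussian-envelope P1 deflection projected as narrower
  bumps over both posterior groups, whose amplitude gains an additive,
  left-lateralized increment on meaning-trained trials;
* optional artifact transients: 200 ms square pulses of +/-100 uV on a random
  channel, designed to trip a +/-75 uV amplitude rejector.

Per-subject alpha and P1 effect sizes are drawn from a bivariate normal
whose correlation is the configured across-subject coupling, so the
downstream alpha/P1 correlation analysis has a known ground truth.

Randomness is organized as one stream per (seed, subject, purpose) so that,
e.g., toggling artifacts does not change the noise realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .errors import ConfigError
from .montage import Montage, default_montage, posterior_patch_montage

TRAINED = "trained"
UNTRAINED = "untrained"
TRIAL_TYPES = ("identical", "same_object_diff_loc", "different_object")

# purpose offsets for per-subject RNG streams
_STREAM_NOISE, _STREAM_ALPHA, _STREAM_ARTIFACT, _STREAM_ORDER = 0, 1, 2, 3
_COHORT_STREAM = 1_000_003


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design
    (16 subjects, 360 same/different trials at 500 Hz, cue->target 1017 ms)."""

    n_subjects: int = 16
    trials_per_condition: int = 180
    sampling_rate: float = 500.0
    epoch_span: tuple[float, float] = (-1500.0, 1500.0)  # ms before cue, after target
    cue_to_target: float = 1017.0  # 150 ms cue + 167 ms mask + 700 ms blank
    noise_exponent: float = 1.0  # spectral slope beta of 1/f^beta background
    noise_scale: float = 10.0  # uV RMS per channel
    alpha_freq: float = 10.0  # Hz, must lie in 8-14
    alpha_base_amp: float = 5.0  # uV
    alpha_effect: float = 0.4  # fractional pre-target amplitude increase, trained
    alpha_effect_window: tuple[float, float] = (-480.0, -250.0)  # ms rel. target
    alpha_topography: np.ndarray | None = None  # per-channel gain; default left-posterior bump
    alpha_topo_sigma: float = 0.45  # rad; angular width of the default alpha bump
    p1_topography: np.ndarray | None = None  # per-channel base gain; default bilateral bumps
    p1_topo_sigma: float = 0.3  # rad; angular width of the P1 bumps
    p1_latency: float = 115.0  # ms post-target
    p1_width: float = 15.0  # ms Gaussian SD
    p1_base_amp: float = 4.0  # uV
    p1_effect: float = 1.5  # additive uV increase, trained
    effect_corr: float = 0.5  # across-subject corr of alpha and P1 effects
    alpha_effect_sd: float | None = None  # default 0.5 * |alpha_effect|
    p1_effect_sd: float | None = None  # default 0.5 * |p1_effect|
    noise_spatial_sigma: float = 0.5  # rad; angular scale of inter-channel mixing
    artifact_rate: float = 0.0  # probability per epoch of a transient
    ramp_ms: float = 50.0  # cosine taper at effect-window edges
    seed: int = 0
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self):
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ConfigError("counts must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigError("artifact_rate must lie in [0, 1]")
        if abs(self.effect_corr) > 1.0:
            raise ConfigError("|effect_corr| must be <= 1")
        if not 8.0 <= self.alpha_freq <= 14.0:
            raise ConfigError("alpha_freq must lie in the 8-14 Hz band")
        w0, w1 = self.alpha_effect_window
        if not w0 < w1:
            raise ConfigError("alpha_effect_window must be ordered (start < end)")
        if w1 > 0:
            raise ConfigError("alpha_effect_window must end at or before target onset")
        if w0 < self.epoch_span[0] - self.cue_to_target:
            raise ConfigError("alpha_effect_window starts before the epoch")
        if self.epoch_span[0] >= 0 or self.epoch_span[1] <= 0:
            raise ConfigError("epoch_span must bracket cue and target")

    # --- derived geometry -------------------------------------------------

    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        t0 = self.epoch_span[0]
        t1 = self.cue_to_target + self.epoch_span[1]
        n = int(np.floor((t1 - t0) / dt)) + 1
        return t0 + dt * np.arange(n)

    def _group_bump(self, group: str, sigma: float) -> np.ndarray:
        """Angular-Gaussian gain profile centred on a channel group's centroid."""
        centroid = self.montage.positions[self.montage.index(group)].mean(axis=0)
        centroid /= np.linalg.norm(centroid)
        theta = np.arccos(np.clip(self.montage.positions @ centroid, -1, 1))
        return np.exp(-0.5 * (theta / sigma) ** 2)

    def _alpha_gain(self) -> np.ndarray:
        if self.alpha_topography is not None:
            g = np.asarray(self.alpha_topography, dtype=float)
            if g.shape != (self.montage.n_channels,):
                raise ConfigError("alpha_topography length != channel count")
            return g
        return self._group_bump("left_posterior", self.alpha_topo_sigma)

    def _mixing_matrix(self) -> np.ndarray | None:
        """Channel-mixing operator giving the noise volume-conduction-like
        spatial correlation; rows have unit L2 norm so per-channel RMS of
        independent inputs is preserved."""
        if self.noise_spatial_sigma <= 0:
            return None
        cosang = np.clip(self.montage.positions @ self.montage.positions.T, -1, 1)
        theta = np.arccos(cosang)
        W = np.exp(-0.5 * (theta / self.noise_spatial_sigma) ** 2)
        return W / np.linalg.norm(W, axis=1, keepdims=True)

    def _p1_gain(self) -> tuple[np.ndarray, np.ndarray]:
        eff = self._group_bump("left_posterior", self.p1_topo_sigma)
        if self.p1_topography is not None:
            base = np.asarray(self.p1_topography, dtype=float)
            if base.shape != (self.montage.n_channels,):
                raise ConfigError("p1_topography length != channel count")
            return base, eff
        base = np.maximum(eff, self._group_bump("right_posterior", self.p1_topo_sigma))
        return base, eff


@dataclass
class GroundTruth:
    """Injected per-subject effects and per-epoch artifact flags."""

    effects: pd.DataFrame  # subject, true_alpha_effect, true_p1_effect, seed
    artifact_flags: dict[int, np.ndarray]
    seed: int

    def to_csv(self, path) -> None:
        self.effects.to_csv(path, index=False)


def desk_scale_config(seed: int = 0, **overrides) -> SimConfig:
    """Reduced-size study conditions for fast simulation experiments.

    20 trials per condition and a shortened epoch (-700 ms pre-cue to
    +300 ms post-target) that still keeps the pre-cue baseline and the
    pre-target analysis window clear of wavelet edge effects. The full
    60-channel montage is retained: with fewer channels the spherical-spline
    Laplacian spreads the focal left-posterior topography far enough to
    contaminate the right hemisphere.
    """
    kwargs = dict(
        trials_per_condition=20,
        epoch_span=(-700.0, 300.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# --- noise ---------------------------------------------------------------


def pink_noise(rng: np.random.Generator, shape, sfreq: float, beta: float,
               rms: float) -> np.ndarray:
    """1/f^beta noise along the last axis with expected RMS ``rms``.

    Spectrum-shaped white Gaussian noise; the scale is set analytically
    (via Parseval) so the expected per-series RMS equals ``rms`` without a
    per-realization normalization pass.
    """
    if rms == 0:
        return np.zeros(shape)
    n = shape[-1]
    from scipy.fft import next_fast_len

    nfft = next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    # E[mean x^2] = (4*sum_{0<k<n/2} amp_k^2 + 2*amp_{n/2}^2) / nfft^2
    interior = amp[1:-1] if nfft % 2 == 0 else amp[1:]
    nyq = amp[-1] if nfft % 2 == 0 else 0.0
    expected_rms = np.sqrt((4 * np.sum(interior**2) + 2 * nyq**2)) / nfft
    amp *= rms / expected_rms
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * amp
    return np.fft.irfft(spec, n=nfft, axis=-1)[..., :n]


# --- effect draws --------------------------------------------------------


def draw_subject_effects(config: SimConfig) -> pd.DataFrame:
    """Per-subject (alpha, P1) effect sizes from a correlated bivariate normal."""
    rng = np.random.default_rng([config.seed, _COHORT_STREAM])
    sa = config.alpha_effect_sd
    sp = config.p1_effect_sd
    if sa is None:
        sa = 0.5 * abs(config.alpha_effect)
    if sp is None:
        sp = 0.5 * abs(config.p1_effect)
    r = config.effect_corr
    z = rng.standard_normal((config.n_subjects, 2))
    alpha = config.alpha_effect + sa * z[:, 0]
    p1 = config.p1_effect + sp * (r * z[:, 0] + np.sqrt(max(0.0, 1 - r * r)) * z[:, 1])
    return pd.DataFrame(
        {
            "subject": np.arange(config.n_subjects),
            "true_alpha_effect": alpha,
            "true_p1_effect": p1,
            "seed": config.seed,
        }
    )


# --- single-subject generation -------------------------------------------


def _effect_envelope(config: SimConfig, times_rel_target: np.ndarray) -> np.ndarray:
    """0..1 window envelope with cosine ramps at both edges."""
    w0, w1 = config.alpha_effect_window
    ramp = min(config.ramp_ms, (w1 - w0) / 2.0)
    t = times_rel_target
    env = np.zeros_like(t)
    if ramp > 0:
        rising = (t >= w0) & (t < w0 + ramp)
        env[rising] = 0.5 * (1 - np.cos(np.pi * (t[rising] - w0) / ramp))
        falling = (t > w1 - ramp) & (t <= w1)
        env[falling] = 0.5 * (1 - np.cos(np.pi * (w1 - t[falling]) / ramp))
    env[(t >= w0 + ramp) & (t <= w1 - ramp)] = 1.0
    return env


def generate_subject(config: SimConfig, subject_index: int,
                     effects: pd.DataFrame | None = None) -> tuple[EpochSet, np.ndarray]:
    """One subject's epochs plus the per-epoch artifact flags.

    Deterministic given (config.seed, subject_index); the per-subject effect
    sizes are drawn from the cohort-level stream so a subject generated alone
    is identical to the same subject inside :func:`generate_cohort`.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError("subject_index out of range")
    if effects is None:
        effects = draw_subject_effects(config)
    alpha_eff = float(effects["true_alpha_effect"].iloc[subject_index])
    p1_eff = float(effects["true_p1_effect"].iloc[subject_index])

    times = config.times_ms()
    t_rel_target = times - config.cue_to_target
    n_samp = len(times)
    n_cond = config.trials_per_condition
    n_trials = 2 * n_cond
    n_ch = config.montage.n_channels

    rng_noise = np.random.default_rng([config.seed, subject_index, _STREAM_NOISE])
    rng_alpha = np.random.default_rng([config.seed, subject_index, _STREAM_ALPHA])
    rng_art = np.random.default_rng([config.seed, subject_index, _STREAM_ARTIFACT])
    rng_order = np.random.default_rng([config.seed, subject_index, _STREAM_ORDER])

    data = pink_noise(
        rng_noise, (n_trials, n_ch, n_samp), config.sampling_rate,
        config.noise_exponent, config.noise_scale,
    )
    mix = config._mixing_matrix()
    if mix is not None and config.noise_scale != 0:
        data = mix @ data  # broadcasts over the trial axis

    # trial labels: first half trained, second untrained, then shuffled
    trained_mask = np.zeros(n_trials, dtype=bool)
    trained_mask[:n_cond] = True
    order = rng_order.permutation(n_trials)
    trained_mask = trained_mask[order]

    # ongoing alpha with condition-dependent amplitude envelope
    if config.alpha_base_amp != 0:
        gain = config._alpha_gain()
        phases = rng_alpha.uniform(0, 2 * np.pi, n_trials)
        carrier = np.sin(
            2 * np.pi * config.alpha_freq * (times / 1000.0)[None, :] + phases[:, None]
        )  # (trials, samples)
        env = _effect_envelope(config, t_rel_target)
        amp = 1.0 + alpha_eff * env[None, :] * trained_mask[:, None]
        data += (config.alpha_base_amp * amp * carrier)[:, None, :] * gain[None, :, None]
    else:
        # keep the phase stream position stable regardless of amplitude
        rng_alpha.uniform(0, 2 * np.pi, n_trials)

    # target-locked P1
    if config.p1_base_amp != 0 or config.p1_effect != 0:
        base_g, eff_g = config._p1_gain()
        bump = np.exp(-0.5 * ((t_rel_target - config.p1_latency) / config.p1_width) ** 2)
        amp_ch = (config.p1_base_amp * base_g[None, :]
                  + p1_eff * trained_mask[:, None] * eff_g[None, :])
        data += amp_ch[:, :, None] * bump[None, None, :]

    # artifact transients
    flags = rng_art.uniform(size=n_trials) < config.artifact_rate
    pulse_len = int(round(0.2 * config.sampling_rate))
    for tr in np.nonzero(flags)[0]:
        ch = rng_art.integers(n_ch)
        start = rng_art.integers(0, max(1, n_samp - pulse_len))
        sign = 1.0 if rng_art.uniform() < 0.5 else -1.0
        data[tr, ch, start:start + pulse_len] += sign * 100.0

    labels = pd.DataFrame(
        {
            "subject": subject_index,
            "condition": np.where(trained_mask, TRAINED, UNTRAINED),
            "trial_type": [TRIAL_TYPES[i % 3] for i in range(n_trials)],
        }
    )
    epochs = EpochSet(
        data=data,
        times_ms=times,
        sfreq=config.sampling_rate,
        target_time_ms=config.cue_to_target,
        labels=labels,
        montage=config.montage,
    )
    return epochs, flags


def generate_cohort(config: SimConfig) -> tuple[list[EpochSet], GroundTruth]:
    """All subjects' epochs plus the ground-truth effect record."""
    effects = draw_subject_effects(config)
    cohort = []
    artifact_flags = {}
    for s in range(config.n_subjects):
        epochs, flags = generate_subject(config, s, effects=effects)
        cohort.append(epochs)
        artifact_flags[s] = flags
    return cohort, GroundTruth(effects=effects, artifact_flags=artifact_flags,
                               seed=config.seed)


def iter_cohort(config: SimConfig):
    """Yield (subject_index, EpochSet, artifact flags) one subject at a time."""
    effects = draw_subject_effects(config)
    for s in range(config.n_subjects):
        epochs, flags = generate_subject(config, s, effects=effects)
        yield s, epochs, flags
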