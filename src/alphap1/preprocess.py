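"""Preprocessing: epoch rejection, filtering, spherical splines, baselining.

The surface Laplacian (current-source-density) estimate follows the
spherical-spline approach of Perrin and colleagues: scalp potential is
interpolated by a spline whose kernel is a Legendre-polynomial series

    g(x) = (1/4pi) * sum_{n>=1} (2n+1) / (n(n+1))^m * P_n(x),

and the surface Laplacian of the interpolant is obtained by multiplying each
degree-n term by n(n+1) (the negated Laplace-Beltrami eigenvalue on the unit
sphere), i.e. with the kernel

    h(x) = (1/4pi) * sum_{n>=1} (2n+1) / (n(n+1))^(m-1) * P_n(x).

With this sign convention a potential pattern that equals a degree-l
spherical harmonic maps to approximately l(l+1) times itself, which is the
usual current-source-density orientation (sources positive). The head is the
unit sphere, so CSD values are in consistent arbitrary units; every
statistic downstream is a condition contrast and therefore invariant to
this overall scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import legval
from scipy.signal import butter, sosfiltfilt

from .epochs import UNITS_CSD, UNITS_VOLT, EpochSet
from .errors import (
    ConfigError,
    NoUsableTrialsError,
    PipelineOrderError,
)
from .montage import Montage

DEFAULT_REJECT_UV = 75.0
DEFAULT_STIFFNESS = 4
DEFAULT_N_LEGENDRE = 50
DEFAULT_LAMBDA = 1e-5


def reject_epochs(epochs: EpochSet, threshold: float = DEFAULT_REJECT_UV
                  ) -> tuple[EpochSet, pd.DataFrame]:
    """Drop epochs whose amplitude strictly exceeds +/-threshold anywhere.

    Returns the surviving epochs (data values bitwise unchanged, order
    preserved) and a per-epoch log with the peak absolute amplitude and the
    keep/reject decision.
    """
    if epochs.units != UNITS_VOLT:
        raise PipelineOrderError("amplitude rejection must run in the uV domain, "
                                 "before the Laplacian")
    if threshold <= 0:
        raise ConfigError("rejection threshold must be positive")
    max_abs = np.abs(epochs.data).max(axis=(1, 2))
    kept = max_abs <= threshold  # strict '>' rejects; exact boundary survives
    log = pd.DataFrame(
        {
            "subject": epochs.labels["subject"],
            "trial": np.arange(epochs.n_trials),
            "max_abs_uV": max_abs,
            "kept": kept,
        }
    )
    if not kept.any():
        subj = epochs.labels["subject"].iloc[0] if epochs.n_trials else "?"
        raise NoUsableTrialsError(f"no usable trials for subject {subj}: "
                                  f"all {epochs.n_trials} epochs rejected")
    return epochs.select_trials(np.nonzero(kept)[0]), log


def bandpass_filter(epochs: EpochSet, low: float = 0.05, high: float = 25.0,
                    order: int = 1) -> EpochSet:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Two-pass application squares the magnitude response of the ``order``-th
    order design and cancels its phase, so component latencies (the P1 peak
    in particular) are not shifted.
    """
    nyq = epochs.sfreq / 2.0
    if not 0 < low < high < nyq:
        raise ConfigError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
                          f"Nyquist ({nyq} Hz)")
    sos = butter(order, [low, high], btype="bandpass", fs=epochs.sfreq, output="sos")
    out = sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.with_data(out, filtered=True)


# --- spherical splines ----------------------------------------------------


def _legendre_kernels(cosang: np.ndarray, m: int, n_legendre: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    n = np.arange(1, n_legendre + 1, dtype=float)
    factor = (2 * n + 1) / (4 * np.pi)
    g_coef = np.concatenate([[0.0], factor / (n * (n + 1)) ** m])
    h_coef = np.concatenate([[0.0], factor / (n * (n + 1)) ** (m - 1)])
    return legval(cosang, g_coef), legval(cosang, h_coef)


def spherical_spline_operators(montage: Montage, m: int = DEFAULT_STIFFNESS,
                               lam: float = DEFAULT_LAMBDA,
                               n_legendre: int = DEFAULT_N_LEGENDRE
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Channel x channel spline smoothing and surface-Laplacian operators.

    The spline coefficients c (and constant c0) for a potential vector v
    solve the ridge-stabilized augmented system [[G + lam*I, 1], [1^T, 0]];
    the returned operators compose that solve with evaluation through g
    (potential) or h (Laplacian), so ``lap_op @ v`` is the CSD estimate at
    every electrode.
    """
    if montage.n_channels < 4:
        raise ConfigError("spherical splines need at least 4 channels")
    if m < 2:
        raise ConfigError("spline stiffness m must be >= 2")
    if lam < 0:
        raise ConfigError("ridge term lambda must be >= 0")
    cosang = montage.cosine_angles()
    G, H = _legendre_kernels(cosang, m, n_legendre)
    nc = montage.n_channels
    A = np.zeros((nc + 1, nc + 1))
    A[:nc, :nc] = G + lam * np.eye(nc)
    A[:nc, nc] = 1.0
    A[nc, :nc] = 1.0
    rhs = np.vstack([np.eye(nc), np.zeros((1, nc))])
    sol = np.linalg.solve(A, rhs)
    C, c0 = sol[:nc], sol[nc]
    interp_op = G @ C + np.outer(np.ones(nc), c0)
    lap_op = H @ C
    return interp_op, lap_op


def apply_laplacian(epochs: EpochSet, montage: Montage | None = None,
                    m: int = DEFAULT_STIFFNESS, lam: float = DEFAULT_LAMBDA,
                    n_legendre: int = DEFAULT_N_LEGENDRE) -> EpochSet:
    """Surface-Laplacian (CSD) transform; flips the unit tag to uV/cm2."""
    if epochs.units != UNITS_VOLT:
        raise PipelineOrderError("Laplacian input must be in uV (applied once)")
    montage = montage or epochs.montage
    if tuple(montage.names) != tuple(epochs.montage.names):
        raise PipelineOrderError("montage channels do not match the epochs")
    _, lap_op = spherical_spline_operators(montage, m=m, lam=lam,
                                           n_legendre=n_legendre)
    out = lap_op @ epochs.data  # broadcasts over the trial axis
    return epochs.with_data(out, units=UNITS_CSD)


def interpolate_channels(epochs: EpochSet, bad: list[str],
                         m: int = DEFAULT_STIFFNESS, lam: float = DEFAULT_LAMBDA,
                         n_legendre: int = DEFAULT_N_LEGENDRE) -> EpochSet:
    """Replace ``bad`` channels by spherical-spline interpolation from the rest."""
    if not bad:
        return epochs
    montage = epochs.montage
    bad_idx = montage.index(bad)
    good_idx = np.setdiff1d(np.arange(montage.n_channels), bad_idx)
    if len(good_idx) < 4:
        raise ConfigError("fewer than 4 good channels left for interpolation")
    pos = montage.positions
    cos_gg = np.clip(pos[good_idx] @ pos[good_idx].T, -1, 1)
    cos_bg = np.clip(pos[bad_idx] @ pos[good_idx].T, -1, 1)
    G_gg, _ = _legendre_kernels(cos_gg, m, n_legendre)
    G_bg, _ = _legendre_kernels(cos_bg, m, n_legendre)
    ng = len(good_idx)
    A = np.zeros((ng + 1, ng + 1))
    A[:ng, :ng] = G_gg + lam * np.eye(ng)
    A[:ng, ng] = 1.0
    A[ng, :ng] = 1.0
    rhs = np.vstack([np.eye(ng), np.zeros((1, ng))])
    sol = np.linalg.solve(A, rhs)
    # map good-channel data directly to interpolated bad-channel data
    M = G_bg @ sol[:ng] + np.outer(np.ones(len(bad_idx)), sol[ng])
    out = epochs.data.copy()
    out[:, bad_idx, :] = np.einsum("bg,tgs->tbs", M, epochs.data[:, good_idx, :])
    return epochs.with_data(out)


def baseline_subtract(epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0),
                      reference_event: str = "target") -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` from the series."""
    if reference_event not in ("cue", "target"):
        raise ConfigError("reference_event must be 'cue' or 'target'")
    mask = epochs.time_mask(window, ref=reference_event)
    if not mask.any():
        raise ConfigError(f"baseline window {window} contains no samples")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.with_data(epochs.data - base)
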