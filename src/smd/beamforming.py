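"""Minimal SAM-style beamformer: pseudo-T contrast maps, omnibus permutation
thresholding and optimized-orientation virtual sensors.

The source model is a volumetric grid of dipoles with a three-orientation
leadfield per grid point.  For each point the dipole orientation is chosen to
maximise beamformer output power relative to projected sensor noise
(generalized eigenvalue problem), weights follow the linearly-constrained
minimum-variance solution w = C^-1 l / (l' C^-1 l) with unit gain at the
target, and the contrast statistic is the pseudo-T

    T = (P_active - P_baseline) / (2 * P_noise),

with P_noise the sensor noise power projected through the weights
(Robinson-Vrba convention).  Active power is averaged over a set of sliding
windows against a fixed baseline window.  Group inference uses the omnibus
max-statistic sign-flip permutation test: each permutation flips the polarity
of whole subject maps, and the (1 - alpha) quantile of the resulting maximum
absolute group mean is the whole-image threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Leadfield:
    """Forward gains: sensors x grid points x 3 orientations."""

    grid: np.ndarray           # (P, 3) grid coordinates, mm
    gain: np.ndarray           # (n_sensors, P, 3)
    spacing: float             # grid spacing, mm
    sensor_positions: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.gain).all():
            raise ValueError("leadfield gains must be finite")
        if self.gain.shape[1] != self.grid.shape[0]:
            raise ValueError("gain/grid point count mismatch")

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_points(self) -> int:
        return self.gain.shape[1]


@dataclass
class PseudoTMap:
    """Pseudo-T value per grid point for one active/baseline contrast."""

    values: np.ndarray         # (P,)
    grid: np.ndarray           # (P, 3)
    active_windows: list[tuple[float, float]]
    baseline_window: tuple[float, float]
    band: tuple[float, float]

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.values))


@dataclass
class VirtualSensor:
    """Beamformer source time series at one grid point."""

    data: np.ndarray           # (trials, samples) or (samples,)
    orientation: np.ndarray    # unit 3-vector
    weights: np.ndarray        # (n_sensors,)
    grid_index: int
    sfreq: float

    def __post_init__(self) -> None:
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("orientation must be unit-norm")


# Window/band presets mirroring the two localiser parameterisations: the
# speech localiser uses 1 s active windows sliding over the first 2 s of the
# trial set against a 2 s inter-trial rest baseline, in an 18-22 Hz band
# (centre of beta); the button-press localiser uses 200 ms active windows
# around the post-movement beta rebound against a 0-200 ms baseline.
PRESETS = {
    "speech": {
        "active_windows": [(o, o + 1.0) for o in np.arange(0.0, 2.0, 0.2)],
        "baseline_window": (-5.0, -3.0),
        "band": (18.0, 22.0),
    },
    "button": {
        "active_windows": [(o, o + 0.2) for o in np.arange(0.6, 0.7, 0.01)],
        "baseline_window": (0.0, 0.2),
        "band": (18.0, 22.0),
    },
}


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

def bandpass_epochs(data: np.ndarray, sfreq: float,
                    band: tuple[float, float] | None) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if band is None:
        return data
    lo, hi = band
    if hi >= sfreq / 2:
        raise ValueError(f"band edge {hi} Hz at/above Nyquist ({sfreq / 2} Hz)")
    if lo <= 0:
        sos = signal.butter(4, hi, btype="low", fs=sfreq, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="band", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def compute_covariance(
    data: np.ndarray,
    times: np.ndarray,
    sfreq: float,
    windows: list[tuple[float, float]] | None = None,
    band: tuple[float, float] | None = None,
    regularization: float = 0.05,
) -> np.ndarray:
    """Band-passed, window-restricted sensor covariance with diagonal loading.

    ``data`` is (trials, channels, samples) or (channels, samples); the
    covariance is pooled over trials and windows and loaded with
    ``regularization`` times the mean sensor power on the diagonal (5%
    default).  With zero regularization a rank-deficient covariance raises.
    """
    X = np.asarray(data, float)
    if X.ndim == 2:
        X = X[None]
    X = bandpass_epochs(X, sfreq, band)
    if windows is None:
        sel = np.ones(len(times), bool)
    else:
        sel = np.zeros(len(times), bool)
        for lo, hi in windows:
            if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
                raise ValueError(f"window ({lo}, {hi}) s outside epoch "
                                 f"({times[0]}, {times[-1]}) s")
            sel |= (times >= lo) & (times < hi)
    Xw = X[:, :, sel]
    n = Xw.shape[0] * Xw.shape[2]
    Xw = Xw - Xw.mean(axis=-1, keepdims=True)
    C = np.einsum("tcs,tds->cd", Xw, Xw) / max(n - 1, 1)
    if regularization > 0:
        C = C + regularization * np.trace(C) / C.shape[0] * np.eye(C.shape[0])
    elif np.linalg.matrix_rank(C) < C.shape[0]:
        raise np.linalg.LinAlgError(
            "covariance is rank-deficient; pass regularization > 0 (diagonal "
            "loading, e.g. 0.05) or supply more data"
        )
    return C


# ---------------------------------------------------------------------------
# Weights and maps
# ---------------------------------------------------------------------------

def beamformer_weights(
    cov: np.ndarray, leadfield_point: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """SAM weights and optimal orientation for one grid point.

    The orientation maximises output source power relative to projected
    noise: the largest generalized eigenvector of (L' C^-1 L, L' C^-2 L).
    The oriented weights satisfy the unit-gain constraint w' l = 1.
    """
    L = np.asarray(leadfield_point, float)  # (n_sensors, 3)
    try:
        Ci = linalg.inv(cov)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("covariance numerically singular") from err
    CiL = Ci @ L
    A = L.T @ CiL            # L' C^-1 L
    B = CiL.T @ CiL          # L' C^-2 L
    A = 0.5 * (A + A.T)
    B = 0.5 * (B + B.T)
    B = B + 1e-10 * np.trace(B) / 3.0 * np.eye(3)  # numerical PD guard
    vals, vecs = linalg.eigh(A, B)
    u = vecs[:, -1]
    u = u / np.linalg.norm(u)
    # deterministic sign: first nonzero component positive
    nz = np.flatnonzero(np.abs(u) > 1e-12)
    if len(nz) and u[nz[0]] < 0:
        u = -u
    l = L @ u
    denom = l @ Ci @ l
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError("degenerate leadfield at grid point")
    w = (Ci @ l) / denom
    return w, u


def _window_covariances(data, times, sfreq, windows, band):
    X = np.asarray(data, float)
    if X.ndim == 2:
        X = X[None]
    X = bandpass_epochs(X, sfreq, band)
    covs = []
    for lo, hi in windows:
        sel = (times >= lo) & (times < hi)
        Xw = X[:, :, sel]
        Xw = Xw - Xw.mean(axis=-1, keepdims=True)
        n = Xw.shape[0] * Xw.shape[2]
        covs.append(np.einsum("tcs,tds->cd", Xw, Xw) / max(n - 1, 1))
    return covs


def pseudo_t_map(
    data: np.ndarray,
    times: np.ndarray,
    sfreq: float,
    leadfield: Leadfield,
    active_windows: list[tuple[float, float]],
    baseline_window: tuple[float, float],
    band: tuple[float, float] = (18.0, 22.0),
    regularization: float = 0.05,
    noise_power: float | None = None,
) -> PseudoTMap:
    """SAM pseudo-T contrast image over the source grid.

    Weights are computed from the covariance of the combined active and
    baseline windows; per sliding active window the pseudo-T is
    (P_active - P_baseline) / (2 * P_noise) with P_noise = sigma^2 ||w||^2,
    sigma^2 estimated as the smallest eigenvalue of the data covariance
    unless given; the map is the arithmetic mean over sliding steps.
    """
    b_lo, b_hi = baseline_window
    for lo, hi in active_windows:
        if lo < b_hi and b_lo < hi:
            raise ValueError(f"baseline window {baseline_window} overlaps active "
                             f"window ({lo}, {hi})")
    cov = compute_covariance(
        data, times, sfreq, windows=list(active_windows) + [baseline_window],
        band=band, regularization=regularization,
    )
    if noise_power is None:
        noise_power = float(linalg.eigvalsh(cov)[0])
    act_covs = _window_covariances(data, times, sfreq, active_windows, band)
    (base_cov,) = _window_covariances(data, times, sfreq, [baseline_window], band)
    values = np.zeros(leadfield.n_points)
    for p in range(leadfield.n_points):
        w, _ = beamformer_weights(cov, leadfield.gain[:, p, :])
        pn = noise_power * (w @ w)
        pb = w @ base_cov @ w
        steps = [(w @ Ca @ w - pb) / (2.0 * pn) for Ca in act_covs]
        values[p] = np.mean(steps)
    return PseudoTMap(values=values, grid=leadfield.grid,
                      active_windows=list(active_windows),
                      baseline_window=baseline_window, band=band)


# ---------------------------------------------------------------------------
# Group omnibus permutation
# ---------------------------------------------------------------------------

def permutation_omnibus(
    group_maps: np.ndarray,
    n_perm: int = 1024,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    two_sided: bool = True,
) -> tuple[float, np.ndarray]:
    """Whole-image max-statistic threshold from sign-flip permutations.

    Each permutation flips the polarity of each subject's entire map with
    probability 1/2, computes the group mean image and records its maximum
    (absolute, when ``two_sided``) value.  The unpermuted statistic is
    included in the null distribution, making the test exact-level.  Returns
    the (1 - alpha) quantile threshold and the boolean mask of voxels whose
    group-mean statistic exceeds it.
    """
    maps = np.atleast_2d(np.asarray(group_maps, float))
    S = maps.shape[0]
    if S < 2:
        warnings.warn("permutation_omnibus with a single subject has a 2-element "
                      "flip universe; p-values are only {0.5, 1}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; threshold estimate will be coarse")
    rng = np.random.default_rng(rng)
    from .tf_decoding import sign_flips
    stat = (lambda m: np.max(np.abs(m))) if two_sided else np.max
    signs = sign_flips(n_perm, S, rng)  # distinct patterns, identity first
    null = np.array([stat((s[:, None] * maps).mean(axis=0)) for s in signs])
    threshold = float(np.quantile(null, 1.0 - alpha, method="higher"))
    observed = maps.mean(axis=0)
    mask = (np.abs(observed) if two_sided else observed) > threshold
    return threshold, mask


# ---------------------------------------------------------------------------
# Virtual sensors
# ---------------------------------------------------------------------------

def virtual_sensor(
    data: np.ndarray, weights: np.ndarray, orientation: np.ndarray,
    grid_index: int, sfreq: float,
) -> VirtualSensor:
    """Project sensor data through beamformer weights: (trials,) ch x samples."""
    X = np.asarray(data, float)
    ts = np.einsum("c,...cs->...s", weights, X)
    return VirtualSensor(data=ts, orientation=np.asarray(orientation, float),
                         weights=np.asarray(weights, float),
                         grid_index=grid_index, sfreq=sfreq)


def virtual_sensor_tf(
    vs_data: np.ndarray,
    sfreq: float,
    freqs: np.ndarray,
    n_cycles: float | np.ndarray = 7.0,
    decim: int = 1,
) -> np.ndarray:
    """Per-trial Morlet spectrograms of a virtual-sensor time series.

    Returns power with shape (trials, times, freqs); ``vs_data`` is
    (trials, samples) or (samples,).  7-cycle Morlet wavelets by default.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, float)
    if np.any(freqs >= sfreq / 2):
        raise ValueError("requested frequency at/above Nyquist")
    X = np.atleast_2d(np.asarray(vs_data, float))[:, None, :]  # (trials, 1, samples)
    power = tfr_array_morlet(X, sfreq=sfreq, freqs=freqs, n_cycles=n_cycles,
                             output="power", decim=decim, verbose="error")
    return np.transpose(power[:, 0, :, :], (0, 2, 1))  # trials x times x freqs
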