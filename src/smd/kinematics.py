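"""Articulatory kinematics: gestural signals, movement segmentation, kinematic profiles.

This module implements the first analysis phase of the speech-motor decoding
pipeline: raw articulator coil tracks (upper lip, lower lip, tongue body plus
fiducial reference coils) are rotated into the occlusal-plane frame of
reference, reduced to one-dimensional gestural signals (bilabial closure BC =
lip aperture, tongue-body constriction TB = tongue-to-nasal-reference
distance), segmented into opening and closing movements via alternating signal
extrema, and summarised by the classical kinematic parameters of speech motor
control: amplitude, duration, peak velocity and stiffness (= peak velocity /
amplitude).

Across many movements these parameters covary lawfully — peak velocity is
close to linear in amplitude, and stiffness falls as a curvilinear function of
duration before flattening into a plateau — and the two resulting profiles
(velocity-vs-amplitude, stiffness-vs-duration) are the behavioural models fed
to the representational similarity analysis further down the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

logger = logging.getLogger(__name__)

# 10%/90% amplitude-level crossing fractions of a raised-cosine movement of
# duration D: solve (1 - cos(pi t / D)) / 2 = 0.1  ->  t/D = acos(0.8)/pi.
RAISED_COSINE_F10 = math.acos(0.8) / math.pi          # ~0.204833
RAISED_COSINE_F90 = 1.0 - RAISED_COSINE_F10           # ~0.795167


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ArticulatoryTrack:
    """Position track of one coil: time (s, strictly increasing) and Nx3 mm."""

    coil_id: str
    time: np.ndarray
    position: np.ndarray  # (n, 3) in mm

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ValueError(f"coil {self.coil_id}: position must be (n, 3)")
        if self.position.shape[0] != self.time.shape[0]:
            raise ValueError(f"coil {self.coil_id}: time/position length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"coil {self.coil_id}: time must be strictly increasing")


@dataclass
class GesturalSignal:
    """One-dimensional gesture magnitude (mm): inter-coil Euclidean distance."""

    gesture_id: str  # "BC" or "TB"
    time: np.ndarray
    magnitude: np.ndarray

    @property
    def sfreq(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class MovementCycle:
    """One opening+closing cycle with its four 10/90% landmark times.

    t1 = onset of opening, t2 = offset of opening, t3 = onset of closing,
    t4 = offset of closing (all interpolated to sub-sample precision).
    Extremum times/values bound the two movements: the cycle runs
    minimum -> maximum -> minimum.
    """

    cycle_index: int
    t1: float
    t2: float
    t3: float
    t4: float
    t_min_start: float
    t_max: float
    t_min_end: float
    v_min_start: float
    v_max: float
    v_min_end: float

    def __post_init__(self) -> None:
        if not (self.t1 < self.t2 <= self.t3 < self.t4):
            raise ValueError(
                f"cycle {self.cycle_index}: landmarks must satisfy t1<t2<=t3<t4, "
                f"got {self.t1:.4f},{self.t2:.4f},{self.t3:.4f},{self.t4:.4f}"
            )


@dataclass
class KinematicRecord:
    """Kinematic parameters of a single opening or closing movement."""

    movement_type: str          # "opening" | "closing"
    cycle_index: int
    amplitude: float            # mm, extremum-to-extremum excursion
    duration: float             # s, extremum-to-extremum (default convention)
    landmark_duration: float    # s, 10-90% landmark span
    peak_velocity: float        # mm/s
    stiffness: float            # 1/s, peak_velocity / amplitude
    onset_time: float           # s, 10% landmark
    valid: bool = True


@dataclass
class KinematicProfile:
    """Cross-movement parameter relationship with its fitted summary."""

    profile_kind: str           # "velocity_vs_amplitude" | "stiffness_vs_duration"
    points: np.ndarray          # (n, 2) of (x, y)
    fit: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Occlusal-frame transform
# ---------------------------------------------------------------------------

def _occlusal_basis(nose: np.ndarray, left: np.ndarray, right: np.ndarray):
    """Rotation+origin so x = posterior-anterior, y = left-right, z = up."""
    origin = 0.5 * (left + right)
    x = nose - origin
    nx = np.linalg.norm(x)
    y_raw = left - right
    if nx < 1e-9 or np.linalg.norm(np.cross(x, y_raw)) < 1e-9 * max(nx, 1.0):
        raise ValueError("reference coils are collinear; occlusal frame undefined")
    x = x / nx
    y = y_raw - (y_raw @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.vstack([x, y, z])  # rows are the new basis vectors
    return R, origin


def transform_to_occlusal_frame(
    tracks: dict[str, ArticulatoryTrack],
    reference_coils: tuple[str, str, str] = ("nose", "left_ear", "right_ear"),
    block_duration: float | None = None,
) -> dict[str, ArticulatoryTrack]:
    """Rigidly transform coil tracks into the occlusal-plane head frame.

    The frame is anchored on three reference (fiducial) coils: origin midway
    between the ear coils, x-axis towards the nose coil (posterior-anterior),
    z-axis superior.  Head motion is corrected blockwise: the transform is
    re-estimated from the reference-coil means of each ``block_duration``
    window (whole recording if None).  Blocks in which a reference coil
    contains NaNs are rejected (output set to NaN) and logged.
    """
    for name in reference_coils:
        if name not in tracks:
            raise KeyError(f"reference coil {name!r} missing from tracks")
    any_track = next(iter(tracks.values()))
    t = any_track.time
    if block_duration is None:
        edges = np.array([t[0], t[-1] + 1e-9])
    else:
        edges = np.arange(t[0], t[-1] + block_duration, block_duration)
        if edges[-1] <= t[-1]:
            edges = np.append(edges, t[-1] + 1e-9)

    out = {
        name: ArticulatoryTrack(tr.coil_id, tr.time.copy(), np.full_like(tr.position, np.nan))
        for name, tr in tracks.items()
    }
    n_rejected = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        if not sel.any():
            continue
        refs = [np.nanmean(tracks[name].position[sel], axis=0) for name in reference_coils]
        block_ok = all(
            np.isfinite(tracks[name].position[sel]).all() for name in reference_coils
        )
        if not block_ok:
            n_rejected += 1
            logger.warning(
                "occlusal transform: reference coil NaN in block [%.3f, %.3f) s; block rejected",
                lo, hi,
            )
            continue
        R, origin = _occlusal_basis(*refs)
        for name, tr in tracks.items():
            out[name].position[sel] = (tr.position[sel] - origin) @ R.T
    if n_rejected:
        logger.info("occlusal transform: %d block(s) rejected", n_rejected)
    return out


# ---------------------------------------------------------------------------
# Gesture construction
# ---------------------------------------------------------------------------

_PLANES = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def compute_gesture(
    track_a: ArticulatoryTrack,
    track_b: ArticulatoryTrack,
    plane: str = "xy",
    gesture_id: str = "BC",
    resample_tolerance: float = 0.5,
) -> GesturalSignal:
    """Pointwise two-dimensional Euclidean inter-coil distance.

    BC (bilabial closure) = upper-lip to lower-lip distance; TB (tongue body
    constriction) = tongue-body to nasal-reference distance.  ``track_b`` is
    linearly resampled onto ``track_a``'s time base; a mismatch in overall
    span larger than ``resample_tolerance`` seconds is an error.
    """
    if plane not in _PLANES:
        raise ValueError(f"plane must be one of {sorted(_PLANES)}")
    ta, tb = track_a.time, track_b.time
    if abs(ta[0] - tb[0]) > resample_tolerance or abs(ta[-1] - tb[-1]) > resample_tolerance:
        raise ValueError("track time bases differ beyond the resampling tolerance")
    i, j = _PLANES[plane]
    pb = np.column_stack(
        [np.interp(ta, tb, track_b.position[:, k]) for k in (i, j)]
    )
    pa = track_a.position[:, (i, j)]
    mag = np.linalg.norm(pa - pb, axis=1)
    return GesturalSignal(gesture_id=gesture_id, time=ta.copy(), magnitude=mag)


# ---------------------------------------------------------------------------
# Movement detection
# ---------------------------------------------------------------------------

def smooth_signal(x: np.ndarray, sfreq: float, cutoff: float | None = 20.0) -> np.ndarray:
    """Zero-phase low-pass (4th-order Butterworth, two-pass)."""
    if cutoff is None or cutoff >= sfreq / 2:
        return np.asarray(x, dtype=float)
    sos = signal.butter(4, cutoff, btype="low", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x)


def _alternating_extrema(x: np.ndarray, min_amplitude: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of alternating minima/maxima with excursions >= min_amplitude.

    Endpoint samples are admitted as extrema so that isolated half-cycles at
    the signal boundary are still segmented.
    """
    maxima, _ = signal.find_peaks(x, prominence=min_amplitude)
    minima, _ = signal.find_peaks(-x, prominence=min_amplitude)
    idx = np.concatenate([maxima, minima])
    kind = np.concatenate([np.ones(len(maxima), bool), np.zeros(len(minima), bool)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]

    # candidate boundary extrema
    if len(idx) == 0:
        lo, hi = int(np.argmin(x)), int(np.argmax(x))
        if x[hi] - x[lo] >= min_amplitude:
            idx = np.array(sorted((lo, hi)))
            kind = np.array([x[i] == x[hi] for i in idx])
        else:
            return np.array([], int), np.array([], bool)
    else:
        first, last = idx[0], idx[-1]
        # boundary extrema: on flat runs take the sample nearest the movement
        if kind[0] and x[first] - x[: first + 1].min() >= min_amplitude:
            seg = x[: first + 1]
            pre = int(np.flatnonzero(seg <= seg.min() + 1e-12)[-1])
            idx, kind = np.insert(idx, 0, pre), np.insert(kind, 0, False)
        elif not kind[0] and x[: first + 1].max() - x[first] >= min_amplitude:
            seg = x[: first + 1]
            pre = int(np.flatnonzero(seg >= seg.max() - 1e-12)[-1])
            idx, kind = np.insert(idx, 0, pre), np.insert(kind, 0, True)
        if kind[-1] and x[last] - x[last:].min() >= min_amplitude:
            post = last + int(np.argmin(x[last:]))
            idx, kind = np.append(idx, post), np.append(kind, False)
        elif not kind[-1] and x[last:].max() - x[last] >= min_amplitude:
            post = last + int(np.argmax(x[last:]))
            idx, kind = np.append(idx, post), np.append(kind, True)

    # enforce strict alternation: within a run of same-type extrema keep the extreme one
    keep_idx, keep_kind = [], []
    for i, k in zip(idx, kind):
        if keep_kind and keep_kind[-1] == k:
            if (k and x[i] > x[keep_idx[-1]]) or (not k and x[i] < x[keep_idx[-1]]):
                keep_idx[-1] = i
        else:
            keep_idx.append(int(i))
            keep_kind.append(bool(k))
    return np.array(keep_idx, int), np.array(keep_kind, bool)


def _crossing_time(t: np.ndarray, x: np.ndarray, i0: int, i1: int, level: float,
                   rising: bool) -> float:
    """First sub-sample crossing of ``level`` in [i0, i1], linear interpolation."""
    seg = x[i0 : i1 + 1]
    if rising:
        above = seg >= level
    else:
        above = seg <= level
    hits = np.nonzero(above)[0]
    if len(hits) == 0:  # level touches the extremum only
        return float(t[i1])
    j = int(hits[0])
    if j == 0:
        return float(t[i0])
    x0, x1 = seg[j - 1], seg[j]
    frac = (level - x0) / (x1 - x0) if x1 != x0 else 0.0
    return float(t[i0 + j - 1] + frac * (t[i0 + j] - t[i0 + j - 1]))


def detect_movements(
    sig: GesturalSignal,
    min_amplitude: float = 1.0,
    min_duration: float = 0.03,
    smooth_cutoff: float | None = 20.0,
) -> list[MovementCycle]:
    """Segment a gestural signal into opening/closing movement cycles.

    Alternating minima and maxima of the (low-pass smoothed) signal delimit
    the movements; within each movement the times at the 10% and 90%
    amplitude levels are linearly interpolated between samples and stored as
    the four cycle landmarks.  Sub-threshold excursions are discarded.  A
    constant signal yields an empty list.
    """
    dt = np.diff(sig.time)
    if np.ptp(dt) > 1e-6 * np.median(dt):
        raise ValueError("detect_movements requires uniform sampling")
    x = smooth_signal(sig.magnitude, sig.sfreq, smooth_cutoff)
    t = sig.time
    idx, kind = _alternating_extrema(x, min_amplitude)
    cycles: list[MovementCycle] = []
    ci = 0
    # a cycle is min -> max -> min
    for k in range(len(idx) - 2):
        if kind[k] or not kind[k + 1] or kind[k + 2]:
            continue
        i_lo0, i_hi, i_lo1 = idx[k], idx[k + 1], idx[k + 2]
        v_lo0, v_hi, v_lo1 = x[i_lo0], x[i_hi], x[i_lo1]
        amp_o, amp_c = v_hi - v_lo0, v_hi - v_lo1
        if amp_o < min_amplitude or amp_c < min_amplitude:
            continue
        if t[i_hi] - t[i_lo0] < min_duration or t[i_lo1] - t[i_hi] < min_duration:
            continue
        t1 = _crossing_time(t, x, i_lo0, i_hi, v_lo0 + 0.1 * amp_o, rising=True)
        t2 = _crossing_time(t, x, i_lo0, i_hi, v_lo0 + 0.9 * amp_o, rising=True)
        t3 = _crossing_time(t, x, i_hi, i_lo1, v_hi - 0.1 * amp_c, rising=False)
        t4 = _crossing_time(t, x, i_hi, i_lo1, v_hi - 0.9 * amp_c, rising=False)
        try:
            cycles.append(
                MovementCycle(
                    cycle_index=ci, t1=t1, t2=t2, t3=t3, t4=t4,
                    t_min_start=float(t[i_lo0]), t_max=float(t[i_hi]),
                    t_min_end=float(t[i_lo1]),
                    v_min_start=float(v_lo0), v_max=float(v_hi), v_min_end=float(v_lo1),
                )
            )
            ci += 1
        except ValueError:
            logger.warning("degenerate landmark ordering near t=%.3f s; cycle skipped", t[i_hi])
    return cycles


# ---------------------------------------------------------------------------
# Kinematic parameters
# ---------------------------------------------------------------------------

def _five_point_velocity(x: np.ndarray, dt: float) -> np.ndarray:
    """5-point central-difference derivative (2nd-order at the edges)."""
    v = np.gradient(x, dt)
    if len(x) >= 5:
        v[2:-2] = (-x[4:] + 8 * x[3:-1] - 8 * x[1:-3] + x[:-4]) / (12 * dt)
    return v


def compute_kinematics(
    sig: GesturalSignal,
    cycle: MovementCycle,
    smooth_cutoff: float | None = 20.0,
    duration_mode: str = "extrema",
    amplitude_floor: float = 1e-6,
) -> list[KinematicRecord]:
    """Amplitude, duration, peak velocity and stiffness of both movements.

    Amplitude is the full excursion between the bounding extrema; duration is
    extremum-to-extremum by default (``duration_mode="landmarks"`` uses the
    10-90% span); peak velocity is the maximum absolute 5-point
    central-difference derivative within the movement, computed on the same
    smoothed signal used for extremum detection; stiffness = peak velocity /
    amplitude.
    """
    if duration_mode not in ("extrema", "landmarks"):
        raise ValueError("duration_mode must be 'extrema' or 'landmarks'")
    x = smooth_signal(sig.magnitude, sig.sfreq, smooth_cutoff)
    t = sig.time
    dt = 1.0 / sig.sfreq
    v = _five_point_velocity(x, dt)
    records = []
    spans = [
        ("opening", cycle.t_min_start, cycle.t_max, cycle.t2 - cycle.t1,
         abs(cycle.v_max - cycle.v_min_start), cycle.t1),
        ("closing", cycle.t_max, cycle.t_min_end, cycle.t4 - cycle.t3,
         abs(cycle.v_max - cycle.v_min_end), cycle.t3),
    ]
    for mtype, ta, tb, lm_dur, amp, onset in spans:
        sel = (t >= ta) & (t <= tb)
        pv = float(np.max(np.abs(v[sel]))) if sel.any() else np.nan
        dur = (tb - ta) if duration_mode == "extrema" else lm_dur
        valid = amp > amplitude_floor and np.isfinite(pv)
        records.append(
            KinematicRecord(
                movement_type=mtype, cycle_index=cycle.cycle_index,
                amplitude=float(amp), duration=float(dur),
                landmark_duration=float(lm_dur), peak_velocity=pv,
                stiffness=pv / amp if valid else np.nan,
                onset_time=float(onset), valid=bool(valid),
            )
        )
    return records


def exclude_outliers(
    records: list[KinematicRecord], n_mad: float = 3.0
) -> tuple[list[KinematicRecord], int]:
    """Drop movements whose amplitude or duration lies beyond median +/- n_mad*MAD.

    Stand-in for the manual speech-error marking of laboratory practice:
    substitutions and lengthy pauses show up as amplitude/duration outliers.
    Returns (retained records, number excluded).
    """
    recs = [r for r in records if r.valid]
    if len(recs) < 3:
        return recs, len(records) - len(recs)
    keep = np.ones(len(recs), bool)
    for attr in ("amplitude", "duration"):
        vals = np.array([getattr(r, attr) for r in recs])
        med = np.median(vals)
        mad = stats.median_abs_deviation(vals, scale="normal")
        if mad > 0:
            keep &= np.abs(vals - med) <= n_mad * mad
    kept = [r for r, k in zip(recs, keep) if k]
    n_excluded = len(records) - len(kept)
    if n_excluded:
        logger.info("excluded %d movement(s) as production errors/outliers", n_excluded)
    return kept, n_excluded


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _powerlaw_plateau(d, a, b, knee):
    d = np.asarray(d, float)
    return np.where(d <= knee, a * d ** b, a * knee ** b)


def _fit_stiffness_duration(x: np.ndarray, y: np.ndarray) -> dict:
    """Monotone curvilinear fit: power-law segment continuing into a plateau."""
    try:
        p0 = (float(np.median(y) * np.median(x)), -1.0, float(np.percentile(x, 75)))
        popt, _ = optimize.curve_fit(
            _powerlaw_plateau, x, y, p0=p0,
            bounds=([1e-12, -4.0, float(np.min(x))], [np.inf, 0.0, float(np.max(x)) * 2]),
            maxfev=20000,
        )
        resid = y - _powerlaw_plateau(x, *popt)
        return {
            "a": float(popt[0]), "exponent": float(popt[1]), "knee": float(popt[2]),
            "plateau": float(popt[0] * popt[2] ** popt[1]),
            "rmse": float(np.sqrt(np.mean(resid ** 2))),
        }
    except RuntimeError:
        return {"a": np.nan, "exponent": np.nan, "knee": np.nan, "plateau": np.nan,
                "rmse": np.nan}


def build_profiles(
    records: list[KinematicRecord],
    movement_type: str | None = None,
) -> tuple[KinematicProfile, KinematicProfile]:
    """Velocity-vs-amplitude (least-squares line) and stiffness-vs-duration
    (power-law + plateau) profiles from >=10 valid movement records.

    ``movement_type`` restricts to "opening" or "closing" (None = both
    jointly, the movement directions being similarly controlled).
    """
    recs = [r for r in records if r.valid]
    if movement_type is not None:
        recs = [r for r in recs if r.movement_type == movement_type]
    if len(recs) < 10:
        raise ValueError(f"need >=10 valid records to fit profiles, got {len(recs)}")
    amp = np.array([r.amplitude for r in recs])
    vel = np.array([r.peak_velocity for r in recs])
    dur = np.array([r.duration for r in recs])
    stf = np.array([r.stiffness for r in recs])

    lin = stats.linregress(amp, vel)
    va = KinematicProfile(
        "velocity_vs_amplitude", np.column_stack([amp, vel]),
        {"slope": float(lin.slope), "intercept": float(lin.intercept),
         "r": float(lin.rvalue)},
    )
    sd = KinematicProfile(
        "stiffness_vs_duration", np.column_stack([dur, stf]),
        _fit_stiffness_duration(dur, stf),
    )
    return va, sd


def records_to_frame(records: list[KinematicRecord]) -> pd.DataFrame:
    """Tabular view (one row per movement) for TSV export."""
    return pd.DataFrame(
        {
            "cycle": [r.cycle_index for r in records],
            "movement_type": [r.movement_type for r in records],
            "onset_time": [r.onset_time for r in records],
            "amplitude": [r.amplitude for r in records],
            "duration": [r.duration for r in records],
            "landmark_duration": [r.landmark_duration for r in records],
            "peak_velocity": [r.peak_velocity for r in records],
            "stiffness": [r.stiffness for r in records],
            "valid": [r.valid for r in records],
        }
    )
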